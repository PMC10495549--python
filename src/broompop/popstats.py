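"""Diversity and differentiation statistics for codominant microsatellite data.

Implements the descriptive layer of the analysis: per-population allelic
diversity, Weir & Cockerham (1984) F-statistics (theta = F_ST, f = F_IS)
with bootstrap-over-loci confidence intervals, Jost's D with Nei-Chesser
unbiased heterozygosities, a three-level nested AMOVA (host crop /
population within host / individuals) on allele-count indicators, great-
circle distances between sampled fields, and Mantel permutation tests for
isolation by distance.

All multi-allele, multi-locus estimators combine variance components by
ratio-of-sums (not mean-of-ratios), matching the usual hierfstat behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeDataset

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DiversitySummary",
    "FStatResult",
    "AmovaResult",
    "DistMatrix",
    "diversity_by_population",
    "wc_fstats",
    "wc_components",
    "jost_d",
    "jost_d_per_locus",
    "amova_nested",
    "great_circle_matrix",
    "pairwise_theta",
    "mantel_test",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversitySummary:
    table: pd.DataFrame  # index=population, columns Na, Ne_alleles, Ho, uHe, n


@dataclass(frozen=True)
class FStatResult:
    theta: float
    f_is: float
    f_it: float
    per_locus: pd.DataFrame  # columns theta, f_is, f_it
    theta_ci: tuple[float, float]
    f_is_ci: tuple[float, float]
    n_boot: int
    degenerate_ci: bool = False


@dataclass(frozen=True)
class AmovaResult:
    table: pd.DataFrame
    # rows: among_groups, among_populations_within_groups, within_populations
    # columns: df, variance_component, phi (with CI columns)
    phi_ct: float
    phi_sc: float
    phi_st: float


@dataclass(frozen=True)
class DistMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# allele bookkeeping
# ---------------------------------------------------------------------------

def _locus_counts(ds: GenotypeDataset, j: int, indices: np.ndarray) -> dict[int, int]:
    """allele -> count among non-missing calls of the given individuals."""
    col = ds.calls[indices, j, :].ravel()
    col = col[col != MISSING]
    alleles, counts = np.unique(col, return_counts=True)
    return dict(zip(alleles.tolist(), counts.tolist()))


def _pop_allele_table(ds: GenotypeDataset, j: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-population allele counts at locus j.

    Returns (counts[pop, allele], n_typed[pop], pop_labels); populations with
    zero typed individuals at the locus are dropped.
    """
    pops = ds.populations
    col = ds.calls[:, j, :]
    alleles = np.unique(col[col != MISSING])
    labels, rows, ns = [], [], []
    for p, idx in pops.items():
        sub = col[idx]
        ok = sub[:, 0] != MISSING
        n = int(ok.sum())
        if n == 0:
            continue
        flat = sub[ok].ravel()
        rows.append([int((flat == a).sum()) for a in alleles])
        ns.append(n)
        labels.append(p)
    return np.asarray(rows, dtype=float), np.asarray(ns, dtype=float), labels


# ---------------------------------------------------------------------------
# per-population diversity
# ---------------------------------------------------------------------------

def diversity_by_population(ds: GenotypeDataset) -> DiversitySummary:
    """Na, effective alleles, Ho and unbiased He per population (locus means).

    Per locus: Ne_alleles = 1 / sum(p^2); Ho = fraction of heterozygous
    calls; uHe = (2n / (2n - 1)) * (1 - sum(p^2)) with n the number of typed
    individuals.  Missing calls are excluded locus-wise; a locus with no
    typed individual in a population is skipped for it (with a warning).
    """
    rows = []
    for p, idx in ds.populations.items():
        na, ne, ho, uhe = [], [], [], []
        for j in range(ds.n_loci):
            col = ds.calls[idx, j, :]
            ok = col[:, 0] != MISSING
            n = int(ok.sum())
            if n == 0:
                warnings.warn(
                    f"population {p}: locus {ds.loci[j].name} has no typed individuals; skipped"
                )
                continue
            flat = col[ok].ravel()
            _, counts = np.unique(flat, return_counts=True)
            freqs = counts / counts.sum()
            sp2 = float((freqs**2).sum())
            na.append(len(counts))
            ne.append(1.0 / sp2)
            ho.append(float((col[ok, 0] != col[ok, 1]).mean()))
            uhe.append((2 * n / (2 * n - 1)) * (1 - sp2) if n > 0 else np.nan)
        rows.append(
            {
                "population": p,
                "n": len(idx),
                "Na": float(np.mean(na)),
                "Ne_alleles": float(np.mean(ne)),
                "Ho": float(np.mean(ho)),
                "uHe": float(np.mean(uhe)),
            }
        )
    table = pd.DataFrame(rows).set_index("population")
    return DiversitySummary(table=table)


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics
# ---------------------------------------------------------------------------

def wc_components(ds: GenotypeDataset) -> np.ndarray:
    """Per-locus Weir-Cockerham variance components summed over alleles.

    Returns an array (n_loci, 3) of (a, b, c): among-population, among-
    individual-within-population, and within-individual components.  Loci
    where fewer than two populations are typed, or that are monomorphic,
    contribute zeros.
    """
    out = np.zeros((ds.n_loci, 3))
    for j in range(ds.n_loci):
        counts, ns, labels = _pop_allele_table(ds, j)
        if len(labels) < 2 or counts.shape[1] < 2:
            continue
        r = len(labels)
        nbar = ns.mean()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        # per-population count of individuals heterozygous for each allele
        pops = ds.populations
        col = ds.calls[:, j, :]
        alleles = np.unique(col[col != MISSING])
        het = np.zeros_like(counts)
        for pi, p in enumerate(labels):
            sub = col[pops[p]]
            sub = sub[sub[:, 0] != MISSING]
            is_het = sub[:, 0] != sub[:, 1]
            for ai, a in enumerate(alleles):
                het[pi, ai] = ((sub == a).any(axis=1) & is_het).sum()
        p_freq = counts / (2 * ns[:, None])
        pbar = (ns[:, None] * p_freq).sum(axis=0) / ns.sum()
        s2 = (ns[:, None] * (p_freq - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = het.sum(axis=0) / ns.sum()
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        out[j] = (a.sum(), b.sum(), c.sum())
    return out


def wc_fstats(
    ds: GenotypeDataset, n_boot: int = 999, seed: int | np.random.Generator = 0
) -> FStatResult:
    """Weir-Cockerham theta (F_ST) and f (F_IS), overall and per locus.

    Overall values are ratio-of-sums over alleles and loci:
    theta = sum(a) / sum(a+b+c), F_IS = 1 - sum(c) / sum(b+c).  Percentile
    95% CIs come from bootstrapping loci (n_boot replicates).
    """
    if len(ds.population_ids) < 2:
        raise ValueError("theta requires at least two populations")
    comp = wc_components(ds)
    polymorphic = np.abs(comp).sum(axis=1) > 0

    def ratios(m: np.ndarray) -> tuple[float, float, float]:
        a, b, c = m.sum(axis=0)
        tot = a + b + c
        theta = a / tot if tot > 0 else np.nan
        f_is = 1 - c / (b + c) if (b + c) > 0 else np.nan
        f_it = 1 - c / tot if tot > 0 else np.nan
        return theta, f_is, f_it

    theta, f_is, f_it = ratios(comp)
    with np.errstate(divide="ignore", invalid="ignore"):
        tot = comp.sum(axis=1)
        bc = comp[:, 1] + comp[:, 2]
        per_locus = pd.DataFrame(
            {
                "locus": [l.name for l in ds.loci],
                "theta": np.where(tot != 0, comp[:, 0] / np.where(tot == 0, 1, tot), np.nan),
                "f_is": np.where(bc != 0, 1 - comp[:, 2] / np.where(bc == 0, 1, bc), np.nan),
                "f_it": np.where(tot != 0, 1 - comp[:, 2] / np.where(tot == 0, 1, tot), np.nan),
            }
        ).set_index("locus")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    degenerate = int(polymorphic.sum()) < 2
    if degenerate:
        warnings.warn("fewer than two polymorphic loci: bootstrap CI is degenerate")
    boots = np.empty((n_boot, 2))
    L = ds.n_loci
    for b_i in range(n_boot):
        pick = rng.integers(L, size=L)
        t, f, _ = ratios(comp[pick])
        boots[b_i] = (t, f)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return FStatResult(
        theta=float(theta),
        f_is=float(f_is),
        f_it=float(f_it),
        per_locus=per_locus,
        theta_ci=(float(lo[0]), float(hi[0])),
        f_is_ci=(float(lo[1]), float(hi[1])),
        n_boot=n_boot,
        degenerate_ci=degenerate,
    )


def pairwise_theta(ds: GenotypeDataset) -> DistMatrix:
    """Pairwise Weir-Cockerham theta between populations (negatives kept)."""
    pops = ds.populations
    labels = list(pops)
    k = len(labels)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = ds.take(np.concatenate([pops[labels[i]], pops[labels[j]]]))
            comp = wc_components(sub)
            a, b, c = comp.sum(axis=0)
            tot = a + b + c
            vals[i, j] = vals[j, i] = a / tot if tot > 0 else 0.0
    return DistMatrix(labels=tuple(labels), values=vals)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def _jost_one_locus(counts: np.ndarray, ns: np.ndarray) -> float:
    """Jost's D from a (pops x alleles) count table; NaN when undefined."""
    k = counts.shape[0]
    if k < 2:
        return np.nan
    p = counts / counts.sum(axis=1, keepdims=True)
    hs = 1.0 - float((p**2).sum(axis=1).mean())
    pbar = p.mean(axis=0)
    ht = 1.0 - float((pbar**2).sum())
    nh = k / (1.0 / ns).sum()
    hs_est = (2 * nh / (2 * nh - 1)) * hs
    ht_est = ht + hs_est / (2 * nh * k)
    if hs_est >= 1.0:
        return np.nan
    return (k / (k - 1)) * (ht_est - hs_est) / (1.0 - hs_est)


def _pop_table_from_indices(
    calls: np.ndarray, j: int, idx_per_pop: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    col = calls[:, j, :]
    alleles = np.unique(col[col != MISSING])
    rows, ns = [], []
    for idx in idx_per_pop:
        sub = col[idx]
        sub = sub[sub[:, 0] != MISSING]
        if len(sub) == 0:
            continue
        flat = sub.ravel()
        rows.append([(flat == a).sum() for a in alleles])
        ns.append(len(sub))
    return np.asarray(rows, dtype=float), np.asarray(ns, dtype=float)


def jost_d_per_locus(ds: GenotypeDataset) -> np.ndarray:
    """Jost's D per locus with Nei-Chesser unbiased H_S and H_T.

    D = (k/(k-1)) (Ht_est - Hs_est) / (1 - Hs_est), with
    Hs_est = (2*nh/(2*nh - 1)) * hs, Ht_est = ht + Hs_est/(2*nh*k),
    nh the harmonic mean sample size and k the number of populations typed
    at the locus.  Loci where Hs_est = 1 are returned as NaN (excluded with
    a warning downstream).
    """
    out = np.full(ds.n_loci, np.nan)
    for j in range(ds.n_loci):
        counts, ns, labels = _pop_allele_table(ds, j)
        if len(labels) < 2:
            continue
        d = _jost_one_locus(counts, ns)
        if np.isnan(d) and len(labels) >= 2:
            warnings.warn(f"locus {ds.loci[j].name}: Hs estimate is 1; locus excluded from D")
        out[j] = d
    return out


def _chao_harmonic_mean(d: np.ndarray) -> float:
    """Variance-corrected harmonic mean across loci (negatives floored at 0)."""
    d = d[~np.isnan(d)]
    if len(d) == 0:
        return float("nan")
    d = np.maximum(d, 0.0)
    m = d.mean()
    if m == 0:
        return 0.0
    v = d.var(ddof=1) if len(d) > 1 else 0.0
    return float(1.0 / (1.0 / m + v * (1.0 / m) ** 3))


def jost_d(
    ds: GenotypeDataset,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Jost's D across loci with a bootstrap CI; optionally per stratum.

    The across-locus summary is the variance-corrected (Chao) harmonic mean
    of per-locus D, after flooring negative per-locus values at zero.  The
    CI bootstraps individuals within populations (n_boot replicates).  When
    ``groups`` maps population -> stratum, D is also computed within each
    stratum that holds >= 2 populations.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    per_locus = jost_d_per_locus(ds)
    overall = _chao_harmonic_mean(per_locus)

    pops = ds.populations
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx_per_pop = [
            idx[rng.integers(len(idx), size=len(idx))] for idx in pops.values()
        ]
        per = np.array(
            [
                _jost_one_locus(*_pop_table_from_indices(ds.calls, j, idx_per_pop))
                for j in range(ds.n_loci)
            ]
        )
        boots[b] = _chao_harmonic_mean(per)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    per_stratum: dict[str, float] = {}
    if groups:
        strata: dict[str, list[str]] = {}
        for p, g in groups.items():
            strata.setdefault(g, []).append(p)
        for g, plist in strata.items():
            if len(plist) < 2:
                continue
            idx = np.concatenate([pops[p] for p in plist if p in pops])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_stratum[g] = _chao_harmonic_mean(jost_d_per_locus(ds.take(idx)))
    return {
        "D": overall,
        "ci_95": ci,
        "per_locus": per_locus,
        "per_stratum": per_stratum,
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# nested AMOVA
# ---------------------------------------------------------------------------

def _amova_ss(y: np.ndarray, pop_code: np.ndarray, grp_code: np.ndarray):
    """Nested sums of squares of one response over individuals."""
    N = len(y)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_w = 0.0
    pop_means = {}
    for p in np.unique(pop_code):
        sel = pop_code == p
        m = y[sel].mean()
        pop_means[p] = (m, sel.sum())
        ss_w += ((y[sel] - m) ** 2).sum()
    ss_g = 0.0
    grp_means = {}
    for g in np.unique(grp_code):
        sel = grp_code == g
        m = y[sel].mean()
        grp_means[g] = (m, sel.sum())
        ss_g += sel.sum() * (m - grand) ** 2
    ss_p = ss_total - ss_w - ss_g
    return ss_g, ss_p, ss_w


def amova_nested(
    ds: GenotypeDataset,
    groups: Mapping[str, str],
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """Three-level AMOVA: among groups / among populations within / within.

    The response variables are per-individual allele-count indicators
    (0/1/2 per allele column, one locus at a time); sums of squares are
    pooled over alleles and loci and converted to variance components with
    the unequal-sample-size coefficients of the standard nested design.
    Phi-statistics are ratios of component sums; their 95% CIs bootstrap
    loci.  Groups holding a single population are pooled into the among-
    population stratum with a warning.
    """
    pop_ids = np.array([s.population_id for s in ds.samples])
    grp_ids = np.array([groups[p] for p in pop_ids])
    # pool singleton groups
    gsizes = pd.Series(
        [groups[p] for p in ds.population_ids]
    ).value_counts()
    singles = set(gsizes[gsizes < 2].index)
    if singles:
        warnings.warn(f"groups with a single population pooled: {sorted(singles)}")
        grp_ids = np.where(np.isin(grp_ids, list(singles)), "_pooled", grp_ids)

    pops = np.unique(pop_ids)
    grps = np.unique(grp_ids)
    N = ds.n_individuals
    n_p = np.array([(pop_ids == p).sum() for p in pops], dtype=float)
    grp_of_pop = np.array([grp_ids[pop_ids == p][0] for p in pops])
    N_g = np.array([(grp_ids == g).sum() for g in grps], dtype=float)

    df_g = len(grps) - 1
    df_p = len(pops) - len(grps)
    df_w = N - len(pops)
    if df_g < 1 or df_p < 1 or df_w < 1:
        raise ValueError("need >= 2 groups, more populations than groups, and replication")

    # coefficients for unequal sizes (three-level nested design)
    sum_np2_within_g = sum(
        (n_p[grp_of_pop == g] ** 2).sum() / N_g[gi] for gi, g in enumerate(grps)
    )
    n_prime = (N - sum_np2_within_g) / df_p
    n_dprime = (sum_np2_within_g - (n_p**2).sum() / N) / df_g
    n_tprime = (N - (N_g**2).sum() / N) / df_g

    def components_per_locus() -> np.ndarray:
        out = np.zeros((ds.n_loci, 3))
        for j in range(ds.n_loci):
            col = ds.calls[:, j, :]
            alleles = np.unique(col[col != MISSING])
            if len(alleles) < 2:
                continue
            ssg = ssp = ssw = 0.0
            for a in alleles:
                y = (col == a).sum(axis=1).astype(float)
                g_, p_, w_ = _amova_ss(y, pop_ids, grp_ids)
                ssg += g_
                ssp += p_
                ssw += w_
            ms_g, ms_p, ms_w = ssg / df_g, ssp / df_p, ssw / df_w
            sig_w = ms_w
            sig_p = (ms_p - ms_w) / n_prime
            sig_g = (ms_g - ms_w - n_dprime * sig_p) / n_tprime
            out[j] = (sig_g, sig_p, sig_w)
        return out

    comp = components_per_locus()

    def phis(m: np.ndarray) -> tuple[float, float, float]:
        sg, sp, sw = m.sum(axis=0)
        tot = sg + sp + sw
        with np.errstate(divide="ignore", invalid="ignore"):
            return sg / tot, sp / (sp + sw), (sg + sp) / tot

    phi_ct, phi_sc, phi_st = phis(comp)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    boots = np.empty((n_boot, 3))
    L = ds.n_loci
    for b in range(n_boot):
        pick = rng.integers(L, size=L)
        boots[b] = phis(comp[pick])
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)

    sg, sp, sw = comp.sum(axis=0)
    table = pd.DataFrame(
        {
            "df": [df_g, df_p, df_w],
            "variance_component": [sg, sp, sw],
            "phi": [phi_ct, phi_sc, phi_st],
            "phi_ci_low": lo,
            "phi_ci_high": hi,
        },
        index=[
            "among_groups",
            "among_populations_within_groups",
            "within_populations",
        ],
    )
    return AmovaResult(table=table, phi_ct=float(phi_ct), phi_sc=float(phi_sc), phi_st=float(phi_st))


# ---------------------------------------------------------------------------
# geography and Mantel
# ---------------------------------------------------------------------------

def great_circle_matrix(coords: Mapping[str, tuple[float, float]]) -> DistMatrix:
    """Haversine great-circle distances (km) between labelled (lat, lon) points.

    Entries with missing coordinates are dropped with a warning.
    """
    labels = []
    pts = []
    for lab, (lat, lon) in coords.items():
        if lat is None or lon is None or np.isnan(lat) or np.isnan(lon):
            warnings.warn(f"{lab}: missing coordinates; excluded from distance matrix")
            continue
        labels.append(lab)
        pts.append((np.radians(lat), np.radians(lon)))
    pts_arr = np.asarray(pts)
    lat = pts_arr[:, 0][:, None]
    lon = pts_arr[:, 1][:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistMatrix(labels=tuple(labels), values=d)


def mantel_test(
    d1: DistMatrix,
    d2: DistMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a permutation p.

    r is the Pearson correlation of the upper triangles; the one-tailed
    p-value is (1 + #{permuted r >= observed}) / (n_perm + 1), permuting
    rows and columns of the second matrix jointly.
    """
    if d1.labels != d2.labels:
        common = [l for l in d1.labels if l in set(d2.labels)]
        if len(common) < 3:
            raise ValueError("matrices share fewer than 3 labels")
        i1 = [d1.labels.index(l) for l in common]
        i2 = [d2.labels.index(l) for l in common]
        d1 = DistMatrix(tuple(common), d1.values[np.ix_(i1, i1)])
        d2 = DistMatrix(tuple(common), d2.values[np.ix_(i2, i2)])
    n = len(d1.labels)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 units")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    if x.std() == 0 or d2.values[iu].std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(m: np.ndarray) -> float:
        y = m[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2.values)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.values[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return r_obs, p
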