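"""Multilocus genotype (clone) analysis for predominantly selfing organisms.

Individuals with identical complete genotypes share a raw MLG; to absorb
genotyping error, raw MLGs are collapsed by complete-linkage (farthest
neighbour) agglomeration on Bruvo's distance, which scores allele
differences in repeat units as 1 - 2^-|dx| and is therefore robust to
single-step scoring slips.  Genotypic diversity is summarized by the MLG
count, the rarefied expected MLG count (hypergeometric eMLG at a common
sample size) and Simpson's lambda, and MLGs are classified as singletons,
host-specific or shared among hosts.  Non-singleton MLGs can be exported as
a Bruvo-distance minimum spanning network.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geno_io import MISSING, GenotypeDataset
from .haplotypes import minimum_spanning_network
from .popstats import DistMatrix

__all__ = [
    "MLGTable",
    "bruvo_distance",
    "bruvo_pair",
    "assign_raw_mlgs",
    "collapse_mlgs",
    "suggest_threshold",
    "genotypic_diversity",
    "classify_sharing",
    "msn_graph",
    "emlg",
]


@dataclass
class MLGTable:
    """Individual -> (raw, collapsed) MLG ids plus the collapse threshold used."""

    individuals: pd.DataFrame  # individual_id, population_id, host_crop, raw_mlg, mlg
    threshold: float

    @property
    def n_mlgs(self) -> int:
        return self.individuals["mlg"].nunique()

    def mlg_of(self) -> pd.Series:
        return self.individuals.set_index("individual_id")["mlg"]


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------

def bruvo_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """Bruvo distance between two diploid single-locus genotypes (repeat counts).

    Allele distance m = 1 - 2^-|dx|; the genotype distance is the minimum
    over the two one-to-one allele pairings of the mean allele distance.
    """
    d = lambda x, y: 1.0 - 2.0 ** (-abs(float(x) - float(y)))
    p1 = (d(g1[0], g2[0]) + d(g1[1], g2[1])) / 2.0
    p2 = (d(g1[0], g2[1]) + d(g1[1], g2[0])) / 2.0
    return min(p1, p2)


def bruvo_distance(ds: GenotypeDataset) -> DistMatrix:
    """Pairwise Bruvo distance between individuals, averaged over loci.

    Requires complete genotypes (filter missing data first) and motif
    lengths on every locus (alleles are converted to repeat counts).
    """
    if (ds.calls == MISSING).any():
        raise ValueError("bruvo_distance requires complete genotypes; run filter_complete")
    reps = ds.repeat_calls().astype(float)
    n, L, _ = reps.shape
    # per locus, distance for both pairings, vectorized over individual pairs
    total = np.zeros((n, n))
    for j in range(L):
        a = reps[:, j, 0][:, None]
        b = reps[:, j, 1][:, None]
        d00 = 1.0 - 2.0 ** (-np.abs(a - a.T))
        d11 = 1.0 - 2.0 ** (-np.abs(b - b.T))
        d01 = 1.0 - 2.0 ** (-np.abs(a - b.T))
        p1 = (d00 + d11) / 2.0
        p2 = (d01 + d01.T) / 2.0
        total += np.minimum(p1, p2)
    vals = total / L
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0  # guard symmetry against fp noise
    return DistMatrix(labels=tuple(s.individual_id for s in ds.samples), values=vals)


# ---------------------------------------------------------------------------
# MLG assignment and collapse
# ---------------------------------------------------------------------------

def assign_raw_mlgs(ds: GenotypeDataset) -> pd.Series:
    """Raw MLG id per individual: identical complete genotypes share an id."""
    keys = [tuple(ds.calls[i].ravel()) for i in range(ds.n_individuals)]
    seen: dict[tuple, int] = {}
    ids = []
    for k in keys:
        if k not in seen:
            seen[k] = len(seen) + 1
        ids.append(seen[k])
    return pd.Series(ids, index=[s.individual_id for s in ds.samples], name="raw_mlg")


def suggest_threshold(dist: DistMatrix) -> float:
    """Largest-gap heuristic for the collapse threshold.

    Places the cutoff in the middle of the widest gap of the sorted unique
    pairwise distances below their median; falls back to 0 when there are
    fewer than two distinct distances there (nothing to separate).
    """
    iu = np.triu_indices(len(dist.labels), k=1)
    vals = np.unique(np.round(dist.values[iu], 12))
    vals = vals[vals <= np.median(dist.values[iu])]
    if len(vals) < 2:
        return 0.0
    gaps = np.diff(vals)
    g = int(np.argmax(gaps))
    return float((vals[g] + vals[g + 1]) / 2.0)


def collapse_mlgs(
    ds: GenotypeDataset,
    dist: DistMatrix | None = None,
    threshold: float | None = None,
) -> MLGTable:
    """Collapse raw MLGs by farthest-neighbour agglomeration on Bruvo distance.

    Clusters are merged only while their maximum pairwise distance stays
    <= threshold (complete linkage), so the collapse is conservative.  With
    threshold 0 the collapsed ids equal the raw ids; with threshold 1 all
    genotypes merge.  When no threshold is given, the largest-gap heuristic
    of :func:`suggest_threshold` is used and recorded in the result.
    """
    raw = assign_raw_mlgs(ds)
    if dist is None:
        dist = bruvo_distance(ds)
    if threshold is None:
        threshold = suggest_threshold(dist)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")

    # collapse acts on unique raw MLGs (represented by their first individual)
    first_idx: dict[int, int] = {}
    for i, r in enumerate(raw.values):
        first_idx.setdefault(int(r), i)
    reps = sorted(first_idx)
    rep_rows = [first_idx[r] for r in reps]
    if len(reps) == 1 or threshold == 0.0:
        mlg_of_raw = {r: r for r in reps}
    else:
        sub = dist.values[np.ix_(rep_rows, rep_rows)]
        z = linkage(squareform(sub, checks=False), method="complete")
        flat = fcluster(z, t=threshold, criterion="distance")
        mlg_of_raw = {r: int(c) for r, c in zip(reps, flat)}

    df = pd.DataFrame(
        {
            "individual_id": [s.individual_id for s in ds.samples],
            "population_id": [s.population_id for s in ds.samples],
            "host_crop": [s.host_crop for s in ds.samples],
            "raw_mlg": raw.values,
            "mlg": [mlg_of_raw[int(r)] for r in raw.values],
        }
    )
    return MLGTable(individuals=df, threshold=float(threshold))


# ---------------------------------------------------------------------------
# genotypic diversity
# ---------------------------------------------------------------------------

def emlg(counts: Sequence[int], g: int) -> float:
    """Expected number of MLGs in a hypergeometric subsample of size g.

    E = sum_i [1 - C(N - n_i, g) / C(N, g)] over MLG counts n_i (N = total).
    For g >= N this equals the observed MLG count.
    """
    counts = [int(c) for c in counts if c > 0]
    N = sum(counts)
    if g >= N:
        return float(len(counts))
    # log-space ratio to stay stable for large N
    def log_comb(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -np.inf
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    lcNg = log_comb(N, g)
    total = 0.0
    for n_i in counts:
        l = log_comb(N - n_i, g)
        total += 1.0 - (np.exp(l - lcNg) if np.isfinite(l) else 0.0)
    return float(total)


def genotypic_diversity(
    mlg: MLGTable, rarefaction_n: int = 50, by: str = "population_id"
) -> pd.DataFrame:
    """Per-unit MLG count, rarefied eMLG and Simpson's lambda.

    ``by`` selects the grouping column (population_id or host_crop).  When a
    unit holds fewer than ``rarefaction_n`` genotypes the eMLG is reported
    at the unit's own size and flagged in the ``rarefied_at`` column.
    """
    rows = []
    for unit, sub in mlg.individuals.groupby(by, sort=False):
        counts = sub["mlg"].value_counts().to_numpy()
        N = int(counts.sum())
        g = min(rarefaction_n, N)
        lam = 1.0 - float(((counts / N) ** 2).sum())
        rows.append(
            {
                by: unit,
                "n": N,
                "mlg_count": len(counts),
                "eMLG": emlg(counts, g),
                "rarefied_at": g,
                "lambda": lam,
            }
        )
    return pd.DataFrame(rows).set_index(by)


def classify_sharing(mlg: MLGTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify collapsed MLGs as singleton / host-specific / shared.

    A singleton is carried by exactly one individual; a host-specific MLG is
    a non-singleton seen in one host only; a shared MLG is a non-singleton
    seen in >= 2 hosts (counted for every host where it occurs).  Returns
    (per-MLG table, per-host tally).
    """
    df = mlg.individuals
    per = (
        df.groupby("mlg")
        .agg(count=("individual_id", "size"), hosts=("host_crop", lambda s: tuple(sorted(set(s)))))
        .reset_index()
    )
    def cls(row):
        if row["count"] == 1:
            return "singleton"
        return "shared" if len(row["hosts"]) >= 2 else "host_specific"

    per["class"] = per.apply(cls, axis=1)
    hosts = sorted(set(df["host_crop"]))
    tally_rows = []
    for h in hosts:
        sub = per[per["hosts"].apply(lambda hs: h in hs)]
        tally_rows.append(
            {
                "host_crop": h,
                "n_individuals": int((df["host_crop"] == h).sum()),
                "singleton": int((sub["class"] == "singleton").sum()),
                "host_specific": int((sub["class"] == "host_specific").sum()),
                "shared": int((sub["class"] == "shared").sum()),
                "total_mlgs": len(sub),
            }
        )
    return per, pd.DataFrame(tally_rows).set_index("host_crop")


# ---------------------------------------------------------------------------
# minimum spanning network over MLGs
# ---------------------------------------------------------------------------

def msn_graph(ds: GenotypeDataset, mlg: MLGTable, include_singletons: bool = False) -> nx.Graph:
    """Bruvo-distance minimum spanning network over collapsed MLGs.

    Nodes are MLG ids carrying the individual count and host composition;
    by convention singletons are excluded (they clutter the network and
    carry no sharing signal) unless ``include_singletons`` is set.
    Each MLG is represented by its first individual's genotype.
    """
    df = mlg.individuals
    counts = df["mlg"].value_counts()
    keep_ids = counts.index if include_singletons else counts[counts > 1].index
    keep_ids = sorted(keep_ids)
    if not keep_ids:
        raise ValueError("no MLGs to build a network from")
    rep_row = {m: df.index[df["mlg"] == m][0] for m in keep_ids}
    rep_idx = [int(rep_row[m]) for m in keep_ids]
    sub = ds.take(rep_idx)
    dist = bruvo_distance(sub)
    labels = [f"MLG{m}" for m in keep_ids]
    g = minimum_spanning_network(labels, dist.values)
    for m, lab in zip(keep_ids, labels):
        members = df[df["mlg"] == m]
        g.nodes[lab]["count"] = int(len(members))
        g.nodes[lab]["hosts"] = ",".join(sorted(set(members["host_crop"])))
    return g
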