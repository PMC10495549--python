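"""Approximate Bayesian computation with random forests (ABC-RF).

Observed and simulated microsatellite datasets are reduced to a named
vector of summary statistics — per deme: mean allele number, mean expected
heterozygosity, mean allele-size variance (repeat units) and mean
Garza-Williamson M; per deme pair: Weir-Cockerham theta, an allele-
frequency shared-allele distance, Goldstein's (delta mu)^2 on repeat counts
and the crossed mean log assignment likelihood.  Scenario choice trains a
classification forest on simulations from each candidate scenario
(optionally augmented with linear discriminant axes); the posterior
probability of the selected scenario is obtained by regressing the
out-of-bag correctness indicator on the summary statistics and evaluating
that regression forest at the observed point.  Parameter estimation uses a
quantile regression forest: the observed point's leaf co-occupancy weights
over training simulations define a weighted posterior sample from which the
median and the 2.5/97.5% quantiles are read, with global and local NMAE
(normalized mean absolute error) computed out-of-bag.

The base statistic set is the 8 families above (4 per deme, 4 per pair);
with three demes that is 24 statistics.  The manifest of statistic names is
carried in every training set so outputs are self-describing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .assignment import build_population_model, genotype_log_likelihoods
from .geno_io import MISSING, GenotypeDataset, LocusDef
from .popstats import wc_components
from .simulate import (
    MutationModel,
    ParamVector,
    ScenarioSpec,
    draw_params,
    simulate_dataset,
)

__all__ = [
    "SumStatVector",
    "TrainingSet",
    "RFResult",
    "ParamEstimate",
    "compute_sumstats",
    "build_training_set",
    "lda_axes",
    "choose_scenario",
    "estimate_params",
    "prior_scenario_check",
]

SumStatVector = pd.Series  # named, fixed-order summary statistics


@dataclass
class TrainingSet:
    stats: pd.DataFrame  # one row per simulation, columns = stat names
    labels: pd.Series  # scenario name per row
    params: pd.DataFrame  # drawn parameters per row (union over scenarios)
    stat_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stats.isna().any().any():
            raise ValueError("training set contains missing summary statistics")

    def subset(self, scenario: str) -> "TrainingSet":
        sel = self.labels == scenario
        return TrainingSet(
            stats=self.stats[sel].reset_index(drop=True),
            labels=self.labels[sel].reset_index(drop=True),
            params=self.params[sel].reset_index(drop=True),
            stat_names=list(self.stat_names),
            provenance=dict(self.provenance),
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# " + json.dumps({"stat_names": self.stat_names, **self.provenance}) + "\n")
            df = pd.concat(
                [self.labels.rename("scenario"), self.params.add_prefix("param:"), self.stats],
                axis=1,
            )
            df.to_csv(fh, sep="\t", index=False)
        return path


@dataclass(frozen=True)
class RFResult:
    votes: pd.Series  # mean vote share per scenario across replicates
    votes_by_replicate: pd.DataFrame
    selected: str
    posterior: float
    global_error: float
    local_error: float
    n_trees: int
    n_replicates: int


@dataclass(frozen=True)
class ParamEstimate:
    table: pd.DataFrame  # per parameter: median, q2.5, q97.5, global_nmae, local_nmae


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _regroup(ds: GenotypeDataset, mapping: Mapping[str, str]) -> GenotypeDataset:
    """Relabel populations into demes (drops populations not in the mapping)."""
    from dataclasses import replace as _replace

    keep = [i for i, s in enumerate(ds.samples) if s.population_id in mapping]
    sub = ds.take(keep)
    samples = [
        _replace(s, population_id=mapping[s.population_id], host_crop=mapping[s.population_id])
        for s in sub.samples
    ]
    return GenotypeDataset(loci=sub.loci, samples=samples, calls=sub.calls.copy())


def compute_sumstats(
    ds: GenotypeDataset, demes: Mapping[str, str] | None = None
) -> SumStatVector:
    """Summary-statistic vector for an observed or simulated dataset.

    ``demes`` maps population_id -> deme label (identity when omitted, i.e.
    each population is a deme).  Statistic order is fixed: per-deme blocks
    in sorted deme order, then per-pair blocks in sorted pair order, so
    vectors from identical partitions are always comparable.
    """
    if demes is not None:
        ds = _regroup(ds, demes)
    pops = ds.populations
    labels = sorted(pops)
    if len(labels) < 2:
        raise ValueError("pairwise statistics need >= 2 demes")
    for d, idx in pops.items():
        if len(idx) < 2:
            raise ValueError(f"deme {d} has fewer than 2 individuals")
    reps = ds.repeat_calls()
    out: dict[str, float] = {}
    per_locus_freqs: dict[str, list[dict[int, float]]] = {}
    per_locus_means: dict[str, np.ndarray] = {}

    for d in labels:
        idx = pops[d]
        na, he, var, gw = [], [], [], []
        means = np.full(ds.n_loci, np.nan)
        freq_list: list[dict[int, float]] = []
        for j in range(ds.n_loci):
            col = reps[idx, j, :]
            flat = col[col != MISSING].astype(float)
            if len(flat) == 0:
                freq_list.append({})
                continue
            alleles, counts = np.unique(flat, return_counts=True)
            p = counts / counts.sum()
            n = len(flat) // 2
            na.append(len(alleles))
            sp2 = float((p**2).sum())
            he.append((2 * n / (2 * n - 1)) * (1 - sp2) if n > 1 else 1 - sp2)
            var.append(float(flat.var(ddof=1)) if len(flat) > 1 else 0.0)
            rng_span = alleles.max() - alleles.min() + 1
            gw.append(len(alleles) / rng_span)
            means[j] = flat.mean()
            freq_list.append(dict(zip(alleles.tolist(), p.tolist())))
        out[f"na_{d}"] = float(np.mean(na))
        out[f"he_{d}"] = float(np.mean(he))
        out[f"vas_{d}"] = float(np.mean(var))
        out[f"gw_{d}"] = float(np.mean(gw))
        per_locus_freqs[d] = freq_list
        per_locus_means[d] = means

    model = build_population_model(ds)
    for i, d1 in enumerate(labels):
        for d2 in labels[i + 1 :]:
            pair_idx = np.concatenate([pops[d1], pops[d2]])
            sub = ds.take(pair_idx)
            comp = wc_components(sub).sum(axis=0)
            tot = comp.sum()
            out[f"theta_{d1}_{d2}"] = float(comp[0] / tot) if tot > 0 else 0.0
            das, dmu = [], []
            for j in range(ds.n_loci):
                f1, f2 = per_locus_freqs[d1][j], per_locus_freqs[d2][j]
                if not f1 or not f2:
                    continue
                shared = sum(min(f1.get(a, 0.0), f2.get(a, 0.0)) for a in set(f1) | set(f2))
                das.append(1.0 - shared)
                dmu.append((per_locus_means[d1][j] - per_locus_means[d2][j]) ** 2)
            out[f"das_{d1}_{d2}"] = float(np.mean(das))
            out[f"dmu2_{d1}_{d2}"] = float(np.mean(dmu))
            # crossed mean log10 assignment likelihood, symmetrized
            i1 = model.pop_labels.index(d1)
            i2 = model.pop_labels.index(d2)
            l12 = genotype_log_likelihoods(model, ds.calls[pops[d1]], i2).mean()
            l21 = genotype_log_likelihoods(model, ds.calls[pops[d2]], i1).mean()
            out[f"aml_{d1}_{d2}"] = float((l12 + l21) / 2.0)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------

def build_training_set(
    scenarios: Sequence[ScenarioSpec],
    n_per_scenario: int = 10_000,
    sample_sizes: Mapping[str, int] | None = None,
    loci: Sequence[LocusDef] | None = None,
    seed: int = 0,
    *,
    mutation: MutationModel | None = None,
    selfing: float = 0.0,
    max_retries: int = 3,
) -> TrainingSet:
    """Simulate the reference table: (scenario, parameters, summary stats).

    Each row gets an independent child stream of the master seed, so the
    table is reproducible and row results do not depend on execution order.
    A simulation that fails (e.g. a degenerate draw) is retried on a fresh
    substream a bounded number of times.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    mutation = mutation or MutationModel()
    n_loci = len(loci) if loci is not None else 10
    stats_rows, label_rows, param_rows = [], [], []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(scenarios) * n_per_scenario)
    r = 0
    for spec in scenarios:
        sizes = dict(sample_sizes or spec.sample_sizes)
        for _ in range(n_per_scenario):
            stream = streams[r]
            r += 1
            for attempt in range(max_retries):
                rng = np.random.default_rng(stream)
                try:
                    pv = draw_params(
                        spec, rng, n_loci=n_loci, mutation=mutation, selfing=selfing
                    )
                    sim = simulate_dataset(
                        spec, pv, sizes, loci, rng, mutation=mutation
                    )
                    stats_rows.append(compute_sumstats(sim))
                    break
                except (ValueError, RuntimeError):
                    stream = stream.spawn(1)[0]
            else:
                raise RuntimeError(f"simulation failed {max_retries} times for {spec.name}")
            label_rows.append(spec.name)
            param_rows.append(pv.as_dict())
    stats = pd.DataFrame(stats_rows).reset_index(drop=True)
    return TrainingSet(
        stats=stats,
        labels=pd.Series(label_rows, name="scenario"),
        params=pd.DataFrame(param_rows).reset_index(drop=True),
        stat_names=list(stats.columns),
        provenance={"seed": seed, "n_per_scenario": n_per_scenario},
    )


def lda_axes(
    ts: TrainingSet, n_axes: int = 3, observed: SumStatVector | None = None
) -> tuple[TrainingSet, SumStatVector | None]:
    """Append linear discriminant axis scores to the training set.

    Axes are fitted on the base statistics with scenario labels; the number
    of informative axes is capped at (number of scenarios - 1).  When an
    observed vector is given it is projected onto the same axes.  The base
    statistic block is left untouched.
    """
    k = ts.labels.nunique()
    if k < 2:
        raise ValueError("LDA axes need >= 2 scenarios")
    n_axes = min(n_axes, k - 1)
    x = ts.stats[ts.stat_names].to_numpy()
    lda = LinearDiscriminantAnalysis(n_components=n_axes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear stats are expected
        z = lda.fit_transform(x, ts.labels.to_numpy())
    stats = ts.stats.copy()
    for a in range(n_axes):
        stats[f"LD{a+1}"] = z[:, a]
    obs_out = None
    if observed is not None:
        zo = lda.transform(observed[ts.stat_names].to_numpy()[None, :])[0]
        obs_out = pd.concat(
            [observed, pd.Series({f"LD{a+1}": zo[a] for a in range(n_axes)})]
        )
    new_ts = TrainingSet(
        stats=stats,
        labels=ts.labels.copy(),
        params=ts.params.copy(),
        stat_names=list(ts.stat_names),
        provenance={**ts.provenance, "lda_axes": n_axes},
    )
    return new_ts, obs_out


# ---------------------------------------------------------------------------
# scenario choice
# ---------------------------------------------------------------------------

def choose_scenario(
    ts: TrainingSet,
    observed: SumStatVector,
    n_trees: int = 1000,
    n_replicates: int = 10,
    seed: int = 0,
    *,
    n_lda: int = 3,
    local_k: int = 500,
) -> RFResult:
    """Random-forest scenario choice with votes, posterior and error rates.

    Classification forests are trained on the summary statistics augmented
    with LDA axes; votes on the observed point are per-tree vote shares
    averaged over ``n_replicates`` forests with distinct seeds.  The
    posterior probability of the selected scenario is the out-of-bag
    correctness indicator regressed on the predictors and evaluated at the
    observed point.  Global error is the OOB misclassification rate; local
    error is the OOB error among the ``local_k`` nearest training points to
    the observation in LDA space.
    """
    missing = [c for c in ts.stat_names if c not in observed.index]
    if missing:
        raise ValueError(f"observed vector lacks statistics: {missing}")
    aug, obs_aug = lda_axes(ts, n_axes=n_lda, observed=observed)
    cols = list(aug.stats.columns)
    x = aug.stats[cols].to_numpy()
    y = aug.labels.to_numpy()
    xo = obs_aug[cols].to_numpy()[None, :]
    classes = sorted(ts.labels.unique())

    rng = np.random.default_rng(seed)
    vote_rows = []
    oob_correct_stack = []
    global_errors = []
    regression_posteriors = []
    local_errors = []
    ld_cols = [c for c in cols if c.startswith("LD")] or cols
    ld_idx = [cols.index(c) for c in ld_cols]
    for rep in range(n_replicates):
        rs = int(rng.integers(2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some rows may never be OOB
            rf = RandomForestClassifier(
                n_estimators=n_trees, oob_score=True, random_state=rs, n_jobs=1
            ).fit(x, y)
        # sub-estimators predict encoded class indices; decode via classes_
        tree_classes = np.array(
            [rf.classes_[int(t.predict(xo)[0])] for t in rf.estimators_]
        )
        share = pd.Series(
            {c: float((tree_classes == c).mean()) for c in classes}, name=f"rep{rep}"
        )
        vote_rows.append(share)
        global_errors.append(1.0 - rf.oob_score_)
        oob_df = rf.oob_decision_function_
        seen = ~np.isnan(oob_df).any(axis=1)
        pred_oob = np.array(rf.classes_)[np.nanargmax(np.where(seen[:, None], oob_df, -1), axis=1)]
        correct = (pred_oob == y).astype(float)
        oob_correct_stack.append((correct, seen, rs))
        # local error: OOB error among nearest neighbours in LDA space
        d = np.linalg.norm(x[:, ld_idx] - xo[:, ld_idx], axis=1)
        nearest = np.argsort(d)[: min(local_k, len(d))]
        sel = nearest[seen[nearest]]
        local_errors.append(1.0 - correct[sel].mean() if len(sel) else np.nan)

    votes_by_rep = pd.DataFrame(vote_rows)
    votes = votes_by_rep.mean(axis=0)
    selected = str(votes.idxmax())

    # posterior: regression forest of the OOB correctness indicator, using
    # correctness pooled across replicates for stability
    correct_mean = np.mean([c for c, s, _ in oob_correct_stack], axis=0)
    reg = RandomForestRegressor(
        n_estimators=min(n_trees, 500), random_state=int(rng.integers(2**31 - 1)), n_jobs=1
    ).fit(x, correct_mean)
    posterior = float(np.clip(reg.predict(xo)[0], 0.0, 1.0))

    return RFResult(
        votes=votes,
        votes_by_replicate=votes_by_rep,
        selected=selected,
        posterior=posterior,
        global_error=float(np.mean(global_errors)),
        local_error=float(np.nanmean(local_errors)),
        n_trees=n_trees,
        n_replicates=n_replicates,
    )


# ---------------------------------------------------------------------------
# parameter estimation (quantile regression forest)
# ---------------------------------------------------------------------------

def _weighted_quantiles(y: np.ndarray, w: np.ndarray, qs: Sequence[float]) -> list[float]:
    order = np.argsort(y)
    y, w = y[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return [float(np.interp(q, cw, y)) for q in qs]


def qrf_intervals(
    ts: TrainingSet,
    observed: pd.DataFrame,
    parameter: str,
    n_trees: int = 500,
    seed: int = 0,
    quantiles: Sequence[float] = (0.025, 0.5, 0.975),
    min_samples_leaf: int = 5,
) -> pd.DataFrame:
    """Quantile-forest posterior quantiles of one parameter at many points.

    Fits a single regression forest on the training set and evaluates the
    leaf-co-occupancy weighted quantiles at every row of ``observed`` (same
    statistic columns as the training set).  Used for calibration studies
    (e.g. interval coverage over many pseudo-observed datasets) where
    refitting per observation would be wasteful.  Quantile forests keep a
    handful of training points per leaf (default 5): single-point leaves
    underestimate the spread of the conditional distribution and make the
    nominal intervals anticonservative.
    """
    x = ts.stats[ts.stat_names].to_numpy()
    y = ts.params[parameter].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        random_state=seed,
        min_samples_leaf=min_samples_leaf,
        n_jobs=1,
    )
    rf.fit(x, y)
    leaves = rf.apply(x)
    xo = observed[ts.stat_names].to_numpy()
    leaf_obs = rf.apply(xo)
    out = np.empty((len(xo), len(quantiles)))
    for r in range(len(xo)):
        w = np.zeros(len(y))
        for t in range(leaves.shape[1]):
            members = leaves[:, t] == leaf_obs[r, t]
            cnt = members.sum()
            if cnt:
                w[members] += 1.0 / cnt
        w /= w.sum()
        out[r] = _weighted_quantiles(y, w, quantiles)
    return pd.DataFrame(out, columns=[f"q{q:g}" for q in quantiles], index=observed.index)


def estimate_params(
    ts: TrainingSet,
    observed: SumStatVector,
    n_trees: int = 1000,
    seed: int = 0,
    *,
    parameters: Sequence[str] | None = None,
    nmae_sample: int = 10_000,
    min_samples_leaf: int = 5,
) -> ParamEstimate:
    """Quantile-regression-forest posterior summaries per parameter.

    For each parameter a regression forest is fitted to the training
    statistics; the weights of training rows sharing leaves with the
    observed point define weighted 2.5/50/97.5% quantiles (point estimate =
    weighted median).  Global NMAE = mean(|OOB prediction - truth| / truth)
    over (a sample of) the training rows; local NMAE re-weights the same
    OOB errors with the observed point's QRF weights.
    """
    if ts.labels.nunique() != 1:
        raise ValueError("parameter estimation expects a single-scenario training set")
    params = list(parameters or ts.params.columns)
    x = ts.stats[ts.stat_names].to_numpy()
    xo = observed[ts.stat_names].to_numpy()[None, :]
    rng = np.random.default_rng(seed)
    rows = []
    for name in params:
        y = ts.params[name].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            raise ValueError(f"parameter {name} is constant in the training set")
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            oob_score=True,
            min_samples_leaf=min_samples_leaf,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(x, y)
        leaves = rf.apply(x)  # (n, T)
        leaf_obs = rf.apply(xo)[0]  # (T,)
        w = np.zeros(len(y))
        for t in range(leaves.shape[1]):
            members = leaves[:, t] == leaf_obs[t]
            cnt = members.sum()
            if cnt:
                w[members] += 1.0 / cnt
        w /= w.sum()
        q025, med, q975 = _weighted_quantiles(y, w, (0.025, 0.5, 0.975))
        oob = rf.oob_prediction_
        valid = ~np.isnan(oob) & (y != 0)
        rel_err = np.abs(oob[valid] - y[valid]) / np.abs(y[valid])
        if len(rel_err) > nmae_sample:
            pick = rng.choice(len(rel_err), size=nmae_sample, replace=False)
            global_nmae = float(rel_err[pick].mean())
        else:
            global_nmae = float(rel_err.mean())
        wv = w[valid]
        local_nmae = float((rel_err * wv).sum() / wv.sum()) if wv.sum() > 0 else np.nan
        rows.append(
            {
                "parameter": name,
                "median": med,
                "q2.5": q025,
                "q97.5": q975,
                "global_nmae": global_nmae,
                "local_nmae": local_nmae,
            }
        )
    return ParamEstimate(table=pd.DataFrame(rows).set_index("parameter"))


# ---------------------------------------------------------------------------
# prior / scenario compatibility check
# ---------------------------------------------------------------------------

def prior_scenario_check(
    spec: ScenarioSpec,
    observed: SumStatVector,
    n_sim: int = 2000,
    seed: int = 0,
    *,
    sample_sizes: Mapping[str, int] | None = None,
    loci: Sequence[LocusDef] | None = None,
    mutation: MutationModel | None = None,
    selfing: float = 0.0,
    flag_bounds: tuple[float, float] = (0.005, 0.995),
) -> pd.DataFrame:
    """Empirical quantile of each observed statistic among prior simulations.

    Statistics falling outside ``flag_bounds`` are flagged: the priors (or
    the scenario) then struggle to reproduce that aspect of the data.
    """
    ts = build_training_set(
        [spec], n_per_scenario=n_sim, sample_sizes=sample_sizes, loci=loci,
        seed=seed, mutation=mutation, selfing=selfing,
    )
    rows = []
    for name in ts.stat_names:
        sims = ts.stats[name].to_numpy()
        q = float((sims < observed[name]).mean() + 0.5 * (sims == observed[name]).mean())
        rows.append(
            {
                "stat": name,
                "observed": float(observed[name]),
                "quantile": q,
                "flagged": not (flag_bounds[0] <= q <= flag_bounds[1]),
            }
        )
    return pd.DataFrame(rows).set_index("stat")
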