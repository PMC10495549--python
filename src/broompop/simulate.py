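"""Coalescent simulation of microsatellite genotypes under divergence scenarios.

The engine simulates, backward in time, the genealogy of sampled gene copies
distributed over demes connected by a rooted tree of divergence ("merge")
events, then drops generalized-stepwise (GSM) mutations on the branches:
mutation counts are Poisson with a per-locus rate, each mutation changes the
repeat count by +/-1 with probability 1-P and otherwise by a geometrically
distributed multi-step, with reflecting boundaries on a contiguous grid of
allele states.  P=0 recovers the strict stepwise model (SMM).

Predominant selfing is modelled as post-hoc autozygosity: at Wright's
equilibrium a selfing rate s gives an identity-by-descent probability
F = s/(2-s) between an individual's two gene copies, so each simulated
individual duplicates a single lineage with probability F and otherwise
carries two independently sampled lineages.

Three scenario builders cover the study designs: the six serial-derivation
topologies over three sampled demes, a four-deme topology with an unsampled
("ghost") deme from which one sampled deme recently derived, and a
study-scale synthetic fixture with populations nested in host-associated
clusters, planted first-generation migrants, and planted admixed (F1)
individuals with ground-truth labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_io import GenotypeDataset, LocusDef, SampleMeta

__all__ = [
    "MutationModel",
    "ScenarioSpec",
    "ParamVector",
    "draw_params",
    "simulate_dataset",
    "build_six_scenarios",
    "build_toy_scenarios",
    "build_ghost_scenario",
    "FixtureConfig",
    "StudyFixture",
    "make_study_fixture",
    "default_loci",
]


# ---------------------------------------------------------------------------
# scenario and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationModel:
    """Prior specification for the GSM mutation process.

    ``mean_rate_bounds`` are uniform prior bounds on the dataset-level mean
    mutation rate (per locus per generation); per-locus rates are drawn from
    a Gamma distribution with shape ``rate_shape`` scaled to that mean.
    ``p_bounds`` are uniform bounds on the geometric multi-step parameter P.
    Set both bounds equal for a fixed value.  ``n_states`` is the number of
    contiguous allele states available to the reflecting random walk.
    """

    mean_rate_bounds: tuple[float, float] = (1e-4, 1e-3)
    rate_shape: float = 2.0
    p_bounds: tuple[float, float] = (0.1, 0.3)
    n_states: int = 40

    def __post_init__(self) -> None:
        if self.mean_rate_bounds[0] <= 0:
            raise ValueError("mutation rate must be > 0")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not (0 <= self.p_bounds[0] <= self.p_bounds[1] < 1):
            raise ValueError("P bounds must satisfy 0 <= lo <= hi < 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """A rooted divergence tree over demes with uniform parameter priors.

    ``demes`` maps deme label -> sample size in diploid individuals (0 for
    ghost/unsampled demes).  ``events`` is a list of (derived_deme,
    source_deme, time_parameter): backward in time, at the named time all
    lineages of the derived deme transfer instantaneously into the source
    deme.  Every deme except the root must appear exactly once as derived.
    ``param_priors`` maps parameter name -> (lower, upper) uniform bounds;
    effective sizes are named ``N_<deme>`` (diploid individuals) and times
    are in generations.  ``constraints`` lists strict inequalities
    (a, b) meaning "a > b" between time parameters, enforced by rejection.
    """

    name: str
    demes: tuple[tuple[str, int], ...]
    events: tuple[tuple[str, str, str], ...]
    param_priors: tuple[tuple[str, tuple[float, float]], ...]
    constraints: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        labels = [d for d, _ in self.demes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate deme labels")
        derived = [e[0] for e in self.events]
        if len(set(derived)) != len(derived):
            raise ValueError("a deme merges more than once")
        if len(self.events) != len(labels) - 1:
            raise ValueError("events must form a rooted tree (n_demes - 1 merges)")
        roots = set(labels) - set(derived)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root deme, got {sorted(roots)}")
        priors = dict(self.param_priors)
        for name, (lo, hi) in priors.items():
            if not lo < hi:
                raise ValueError(f"prior {name}: lower must be < upper")
        for d in labels:
            if f"N_{d}" not in priors:
                raise ValueError(f"missing effective-size prior N_{d}")
        for _, _, t in self.events:
            if t not in priors:
                raise ValueError(f"missing time prior {t}")
        for a, b in self.constraints:
            if a not in priors or b not in priors:
                raise ValueError(f"constraint ({a} > {b}) names unknown parameter")

    @property
    def priors(self) -> dict[str, tuple[float, float]]:
        return dict(self.param_priors)

    @property
    def sampled_demes(self) -> list[str]:
        return [d for d, n in self.demes if n > 0]

    @property
    def sample_sizes(self) -> dict[str, int]:
        return {d: n for d, n in self.demes if n > 0}

    @property
    def root(self) -> str:
        derived = {e[0] for e in self.events}
        return next(d for d, _ in self.demes if d not in derived)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "demes": list(map(list, self.demes)),
                "events": list(map(list, self.events)),
                "param_priors": {k: list(v) for k, v in self.param_priors},
                "constraints": list(map(list, self.constraints)),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "ScenarioSpec":
        d = json.loads(text)
        return ScenarioSpec(
            name=d["name"],
            demes=tuple((a, int(b)) for a, b in d["demes"]),
            events=tuple(tuple(e) for e in d["events"]),
            param_priors=tuple((k, (float(v[0]), float(v[1]))) for k, v in d["param_priors"].items()),
            constraints=tuple(tuple(c) for c in d.get("constraints", [])),
        )


@dataclass(frozen=True)
class ParamVector:
    """One draw of demographic and mutational parameters."""

    values: tuple[tuple[str, float], ...]  # N_<deme> and time parameters
    locus_rates: tuple[float, ...]
    p_gsm: float
    selfing: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.selfing < 1):
            raise ValueError("selfing rate must be in [0, 1)")
        if not (0 <= self.p_gsm < 1):
            raise ValueError("GSM P must be in [0, 1)")
        for k, v in self.values:
            if v <= 0:
                raise ValueError(f"parameter {k} must be positive, got {v}")

    def __getitem__(self, key: str) -> float:
        return dict(self.values)[key]

    @property
    def autozygosity(self) -> float:
        """Wright's equilibrium F = s / (2 - s)."""
        return self.selfing / (2.0 - self.selfing)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def draw_params(
    spec: ScenarioSpec,
    seed: int | np.random.Generator,
    *,
    n_loci: int = 10,
    mutation: MutationModel | None = None,
    selfing: float = 0.0,
    max_tries: int = 10_000,
) -> ParamVector:
    """Draw a parameter vector from the scenario priors.

    Time-order constraints are enforced by rejection sampling (redraw the
    whole vector).  Reproducible for a fixed integer seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mutation = mutation or MutationModel()
    priors = spec.priors
    for _ in range(max_tries):
        vals = {k: rng.uniform(lo, hi) for k, (lo, hi) in priors.items()}
        if all(vals[a] > vals[b] for a, b in spec.constraints):
            mu_lo, mu_hi = mutation.mean_rate_bounds
            mu_mean = rng.uniform(mu_lo, mu_hi) if mu_hi > mu_lo else mu_lo
            shape = mutation.rate_shape
            rates = rng.gamma(shape, mu_mean / shape, size=n_loci)
            rates = np.clip(rates, mu_mean / 100.0, None)
            p_lo, p_hi = mutation.p_bounds
            p = rng.uniform(p_lo, p_hi) if p_hi > p_lo else p_lo
            return ParamVector(
                values=tuple(sorted(vals.items())),
                locus_rates=tuple(float(r) for r in rates),
                p_gsm=float(p),
                selfing=float(selfing),
            )
    raise RuntimeError(
        f"could not satisfy constraints of scenario {spec.name!r} in {max_tries} draws"
    )


# ---------------------------------------------------------------------------
# coalescent engine
# ---------------------------------------------------------------------------

def _simulate_genealogy(
    rng: np.random.Generator,
    copies_per_deme: dict[str, int],
    ne: dict[str, float],
    events: Sequence[tuple[str, str, float]],
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Simulate one genealogy; returns (parent, branch_length, leaf ids per deme).

    Continuous-time coalescent: within a deme holding k lineages the waiting
    time to the next coalescence is Exp(k(k-1)/(4N)) generations.  Merge
    events transfer all lineages of the derived deme into the source deme.
    """
    n_leaves = sum(copies_per_deme.values())
    max_nodes = 2 * n_leaves - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    node_time = np.zeros(max_nodes)
    lineages: dict[str, list[int]] = {}
    leaf_ids: dict[str, np.ndarray] = {}
    nid = 0
    for deme, k in copies_per_deme.items():
        ids = list(range(nid, nid + k))
        lineages[deme] = ids
        leaf_ids[deme] = np.asarray(ids, dtype=np.int64)
        nid += k

    ev = sorted(events, key=lambda e: e[2])
    epochs = [e[2] for e in ev] + [math.inf]
    t = 0.0
    for epoch_i, t_end in enumerate(epochs):
        # coalesce each deme independently up to t_end
        for deme, lin in lineages.items():
            td = t
            while len(lin) >= 2:
                k = len(lin)
                rate = k * (k - 1) / (4.0 * ne[deme])
                td += rng.exponential(1.0 / rate)
                if td > t_end:
                    break
                i, j = sorted(rng.choice(k, size=2, replace=False))
                parent[lin[i]] = parent[lin[j]] = nid
                node_time[nid] = td
                # replace child i by the parent, drop child j by swap-pop
                lin[i] = nid
                lin[j] = lin[-1]
                lin.pop()
                nid += 1
        if epoch_i < len(ev):
            derived, source, _ = ev[epoch_i]
            lineages.setdefault(source, []).extend(lineages.pop(derived, []))
            t = t_end
    root = nid - 1
    blen = np.zeros(max_nodes)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent[: nid], blen[: nid], leaf_ids


def _reflect(x: np.ndarray | int, n_states: int) -> np.ndarray | int:
    """Fold an integer position onto [0, n_states-1] by reflection."""
    period = 2 * (n_states - 1)
    y = np.mod(x, period)
    return np.where(y > n_states - 1, period - y, y)


def _drop_mutations(
    rng: np.random.Generator,
    parent: np.ndarray,
    blen: np.ndarray,
    rate: float,
    p_gsm: float,
    n_states: int,
) -> np.ndarray:
    """Assign allele states (0..n_states-1) to all nodes, root state centered."""
    n = len(parent)
    states = np.empty(n, dtype=np.int64)
    root = n - 1  # parents are created after children; last node is the root
    states[root] = (n_states - 1) // 2
    n_mut = rng.poisson(rate * blen)
    for v in range(n - 2, -1, -1):
        s = states[parent[v]]
        m = n_mut[v]
        if m:
            if p_gsm > 0:
                mags = rng.geometric(1.0 - p_gsm, size=m)
            else:
                mags = np.ones(m, dtype=np.int64)
            signs = rng.choice((-1, 1), size=m)
            for step in mags * signs:
                s = int(_reflect(s + step, n_states))
        states[v] = s
    return states


def simulate_dataset(
    spec: ScenarioSpec,
    params: ParamVector,
    sample_sizes: Mapping[str, int] | None = None,
    loci: Sequence[LocusDef] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    mutation: MutationModel | None = None,
    id_prefix: str = "sim",
) -> GenotypeDataset:
    """Simulate one diploid microsatellite dataset under a divergence scenario.

    Each sampled deme becomes one population in the output (host crop label =
    deme label).  Allele sizes are ``offset + motif_length * (base + state)``
    on the locus's repeat grid.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mutation = mutation or MutationModel()
    sizes = dict(sample_sizes) if sample_sizes is not None else spec.sample_sizes
    for d, n in sizes.items():
        if n < 1:
            raise ValueError(f"sample size for deme {d} must be >= 1")
    loci = list(loci) if loci is not None else default_loci(len(params.locus_rates), n_states=mutation.n_states)
    if len(loci) != len(params.locus_rates):
        raise ValueError("number of loci must match params.locus_rates")
    vals = params.as_dict()
    ne = {d: vals[f"N_{d}"] for d, _ in spec.demes}
    for d, v in ne.items():
        if v <= 0:
            raise ValueError(f"effective size of deme {d} must be > 0")
    events = [(dv, src, vals[t]) for dv, src, t in spec.events]
    copies = {d: 2 * sizes.get(d, 0) for d, _ in spec.demes}  # ghosts hold 0 copies
    F = params.autozygosity

    n_ind = sum(sizes.values())
    calls = np.empty((n_ind, len(loci), 2), dtype=np.int64)
    # individual layout: deme by deme in spec order, copies 2i, 2i+1
    deme_order = [d for d, _ in spec.demes if sizes.get(d, 0) > 0]
    auto = rng.random(n_ind) < F
    for j, locus in enumerate(loci):
        parent, blen, leaf_ids = _simulate_genealogy(rng, copies, ne, events)
        states = _drop_mutations(
            rng, parent, blen, params.locus_rates[j], params.p_gsm, mutation.n_states
        )
        base = _grid_base(locus, mutation.n_states)
        row = 0
        for d in deme_order:
            ids = leaf_ids[d]
            for i in range(sizes[d]):
                a = states[ids[2 * i]]
                b = states[ids[2 * i + 1]]
                if auto[row]:
                    b = a
                calls[row, j, 0] = locus.offset + locus.motif_length * (base + a)
                calls[row, j, 1] = locus.offset + locus.motif_length * (base + b)
                row += 1
    samples = [
        SampleMeta(individual_id=f"{id_prefix}_{d}_{i:04d}", population_id=d, host_crop=d)
        for d in deme_order
        for i in range(sizes[d])
    ]
    return GenotypeDataset(loci=loci, samples=samples, calls=calls)


def _grid_base(locus: LocusDef, n_states: int) -> int:
    """Lowest repeat count of the simulation grid, kept inside allele_range."""
    lo_rep = (locus.allele_range[0] - locus.offset + locus.motif_length - 1) // locus.motif_length
    hi_rep = (locus.allele_range[1] - locus.offset) // locus.motif_length
    if hi_rep - lo_rep + 1 < n_states:
        raise ValueError(
            f"locus {locus.name}: allele_range too narrow for {n_states} states"
        )
    return lo_rep


def default_loci(n_loci: int, motif_length: int = 2, n_states: int = 40) -> list[LocusDef]:
    """Loci with a repeat grid of ``n_states`` states starting at 10 repeats."""
    lo, hi = 10 * motif_length, (10 + n_states - 1) * motif_length
    return [
        LocusDef(name=f"SSR{j+1:02d}", motif_length=motif_length, allele_range=(lo, hi))
        for j in range(n_loci)
    ]


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def _ne_priors(labels: Sequence[str], bounds=(10.0, 1000.0)):
    return [(f"N_{d}", bounds) for d in labels]


def build_six_scenarios(
    labels: Sequence[str] = ("OR", "TB", "HP"),
    sample_sizes: Mapping[str, int] | None = None,
    *,
    ancient_bounds: tuple[float, float] = (100.0, 100_000.0),
    recent_bounds: tuple[float, float] = (10.0, 10_000.0),
    ne_bounds: tuple[float, float] = (10.0, 1000.0),
) -> list[ScenarioSpec]:
    """The six serial-derivation scenarios over three sampled demes.

    Choose the anciently diverging pair (3 ways), then which member of that
    pair spawns the third deme at the recent time (2 ways).  Default priors:
    ancient time U[100, 100000] generations, recent time U[10, 10000], all
    effective sizes U[10, 1000]; the ancient time is constrained to exceed
    the recent one.
    """
    labels = list(labels)
    if len(labels) != 3:
        raise ValueError("exactly 3 deme labels required")
    sizes = dict(sample_sizes or {d: 25 for d in labels})
    out = []
    for x, y in combinations(labels, 2):
        z = next(d for d in labels if d not in (x, y))
        for parent in (x, y):
            name = f"ancient_{x}_{y}__{z}_from_{parent}"
            out.append(
                ScenarioSpec(
                    name=name,
                    demes=tuple((d, sizes[d]) for d in labels),
                    events=(
                        (z, parent, "t_recent"),
                        (y, x, "t_ancient"),
                    ),
                    param_priors=tuple(
                        _ne_priors(labels, ne_bounds)
                        + [("t_ancient", ancient_bounds), ("t_recent", recent_bounds)]
                    ),
                    constraints=(("t_ancient", "t_recent"),),
                )
            )
    return out


def build_toy_scenarios(
    labels: Sequence[str] = ("OR", "TB", "HP"),
    sample_sizes: Mapping[str, int] | None = None,
) -> list[ScenarioSpec]:
    """Six three-deme scenarios engineered to be mutually distinguishable.

    Same six topologies as :func:`build_six_scenarios`, but with narrow,
    well-separated priors: the recently derived deme passes through a small
    effective size (U[20, 60]) while the others stay large (U[300, 500]),
    and the two divergence times are tightly bounded (ancient U[8000, 12000],
    recent U[50, 150]).  Each scenario then leaves a distinct signature —
    which deme pair split recently and which deme lost diversity — which is
    what desk-scale forest-classification checks need.
    """
    base = build_six_scenarios(labels, sample_sizes)
    out = []
    for spec in base:
        derived = spec.events[0][0]
        priors = []
        for name, bounds in spec.param_priors:
            if name == f"N_{derived}":
                priors.append((name, (20.0, 60.0)))
            elif name.startswith("N_"):
                priors.append((name, (300.0, 500.0)))
            elif name == "t_ancient":
                priors.append((name, (8000.0, 12_000.0)))
            else:  # t_recent
                priors.append((name, (50.0, 150.0)))
        out.append(
            ScenarioSpec(
                name=spec.name,
                demes=spec.demes,
                events=spec.events,
                param_priors=tuple(priors),
                constraints=spec.constraints,
            )
        )
    return out


def build_ghost_scenario(
    labels: Sequence[str] = ("OR", "TB", "HP"),
    sample_sizes: Mapping[str, int] | None = None,
    *,
    ne_bounds: tuple[float, float] = (10.0, 1000.0),
    ancient_bounds: tuple[float, float] = (1000.0, 50_000.0),
    tb_hp_bounds: tuple[float, float] = (10.0, 5000.0),
    or_ghost_bounds: tuple[float, float] = (10.0, 1000.0),
) -> ScenarioSpec:
    """Four-deme scenario with an unsampled ghost lineage.

    Backward in time: OR merges into the ghost at t_OR_ghost (U[10, 1000]);
    TB merges into HP at t_TB_HP (U[10, 5000]); the ghost merges into HP at
    t_ancient (U[1000, 50000]).  All effective sizes U[10, 1000].
    """
    orl, tbl, hpl = labels
    sizes = dict(sample_sizes or {d: 25 for d in labels})
    return ScenarioSpec(
        name="ghost_origin",
        demes=((orl, sizes[orl]), (tbl, sizes[tbl]), (hpl, sizes[hpl]), ("ghost", 0)),
        events=(
            (orl, "ghost", "t_OR_ghost"),
            (tbl, hpl, "t_TB_HP"),
            ("ghost", hpl, "t_ancient"),
        ),
        param_priors=tuple(
            _ne_priors([orl, tbl, hpl, "ghost"], ne_bounds)
            + [
                ("t_ancient", ancient_bounds),
                ("t_TB_HP", tb_hp_bounds),
                ("t_OR_ghost", or_ghost_bounds),
            ]
        ),
        constraints=(("t_ancient", "t_TB_HP"), ("t_ancient", "t_OR_ghost")),
    )


# ---------------------------------------------------------------------------
# study-scale synthetic fixture
# ---------------------------------------------------------------------------

HOST_LABELS = ("oilseed_rape_FR", "tobacco", "hemp", "lentil", "tomato", "celery", "oilseed_rape_GR")


@dataclass(frozen=True)
class FixtureConfig:
    """Study-scale synthetic dataset layout.

    Defaults emulate the study conditions: 10 SSR loci, populations of 11
    individuals nested in host-associated clusters, selfing-level inbreeding
    (autozygosity 0.887, i.e. selfing rate ~0.94), ~9% first-generation
    migrants and ~3% admixed (F1 outcross) individuals.  Cluster divergence
    times and effective sizes are set so that the fixture shows strong
    among-host differentiation with much weaker, but present, among-
    population-within-host structure and low within-population diversity.
    """

    n_clusters: int = 5
    pops_per_cluster: int = 15
    n_per_pop: int = 11
    n_loci: int = 10
    migrant_rate: float = 0.09
    migrant_same_cluster_prob: float = 0.8
    admixture_rate: float = 0.03
    admixed_selfing_generations: int = 0
    selfing: float = 0.97
    ne_pop: float = 60.0
    ne_cluster: float = 200.0
    ne_sibling_anc: float = 50.0
    t_pop: float = 60.0
    t_pop_sibling: float = 5.0
    t_cluster_recent: float = 2000.0
    t_cluster_spacing: float = 1500.0
    t_sibling: float = 1000.0
    t_or_ghost: float = 400.0
    t_ancient: float = 20_000.0
    mu: float = 2.5e-4
    p_gsm: float = 0.2
    n_states: int = 40

    def __post_init__(self) -> None:
        if not 3 <= self.n_clusters <= 7:
            raise ValueError("n_clusters must be in 3..7")
        if self.migrant_rate + self.admixture_rate >= 1:
            raise ValueError("migrant + admixture rates must be < 1")


@dataclass
class StudyFixture:
    dataset: GenotypeDataset
    truth: pd.DataFrame  # individual_id, population_id, cluster, is_migrant, source_population, is_admixed, donor_population
    config: FixtureConfig


def _fixture_scenario(cfg: FixtureConfig, pops: list[str], cluster_of: dict[str, str]) -> tuple[list, dict]:
    """Events and fixed parameter values for the fixture's divergence tree."""
    clusters = list(dict.fromkeys(cluster_of.values()))
    # fields of the sibling pair exchange more (shared genotypes across
    # fields), hence much weaker per-field drift than the other clusters
    sibling_clusters = {clusters[1], clusters[-1]} if len(clusters) > 2 else set()
    events: list[tuple[str, str, float]] = []
    ne: dict[str, float] = {}
    for p in pops:
        t_split = cfg.t_pop_sibling if cluster_of[p] in sibling_clusters else cfg.t_pop
        events.append((p, f"anc_{cluster_of[p]}", t_split))
        ne[p] = cfg.ne_pop
    for c in clusters:
        ne[f"anc_{c}"] = cfg.ne_cluster
    ne["ghost"] = cfg.ne_cluster
    if len(clusters) > 2:
        # small sibling-branch size drives near-fixed differences between
        # the sibling pair, so their F1s sit squarely between the clusters
        ne[f"anc_{clusters[-1]}"] = cfg.ne_sibling_anc
    # cluster 0 is the divergent (ghost-derived) lineage; cluster 1 is the
    # backbone; intermediate clusters attach at staggered deep times; the
    # LAST cluster is the backbone's recently diverged sibling — the only
    # cluster pair close enough for admixed genotypes to look intermediate
    a = [f"anc_{c}" for c in clusters]
    events.append((a[0], "ghost", cfg.t_or_ghost))
    events.append(("ghost", a[1], cfg.t_ancient))
    for k in range(2, len(a) - 1):
        events.append((a[k], a[1], cfg.t_cluster_recent + (k - 2) * cfg.t_cluster_spacing))
    if len(a) > 2:
        events.append((a[-1], a[1], cfg.t_sibling))
    return events, ne


def make_study_fixture(
    config: FixtureConfig | None = None, seed: int | np.random.Generator = 0
) -> StudyFixture:
    """Generate the synthetic stand-in for the deposited study genotypes.

    Populations are simulated jointly on one divergence tree (populations
    nested within host clusters, one divergent ghost-derived cluster).  A
    fraction of individuals are replaced by first-generation migrants (their
    genotype is drawn from a uniformly chosen other population) and another
    fraction by admixed F1 individuals (one gene copy from the home
    population, one from a donor population in a different cluster).  Truth
    labels for cluster, migrant status/source and admixture are returned
    alongside the genotypes.
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    hosts = list(HOST_LABELS[: cfg.n_clusters])
    pops: list[str] = []
    cluster_of: dict[str, str] = {}
    for ci, host in enumerate(hosts):
        for k in range(cfg.pops_per_cluster):
            p = f"P{ci * cfg.pops_per_cluster + k + 1:03d}"
            pops.append(p)
            cluster_of[p] = host

    # plan individual statuses
    statuses: list[tuple[str, str, str | None, str | None]] = []
    # (home_pop, kind, source_pop, donor_pop) with kind in resident/migrant/admixed
    other_cluster_pops = {
        c: [p for p in pops if cluster_of[p] != c] for c in hosts
    }
    same_cluster_pops = {
        p: [q for q in pops if cluster_of[q] == cluster_of[p] and q != p] for p in pops
    }
    # admixture happens only between the sibling cluster pair (hosts[1] and
    # hosts[-1]); the within-pair rate is scaled so the dataset-wide admixed
    # fraction matches admixture_rate
    sibling_pair = {hosts[1], hosts[-1]} if len(hosts) > 2 else set()
    sibling_of = {hosts[1]: hosts[-1], hosts[-1]: hosts[1]} if sibling_pair else {}
    pair_rate = cfg.admixture_rate * len(hosts) / 2.0 if sibling_pair else 0.0
    for p in pops:
        in_pair = cluster_of[p] in sibling_pair
        for _ in range(cfg.n_per_pop):
            u = rng.random()
            if u < cfg.migrant_rate:
                # migration is mostly host-constrained: sources are usually
                # other fields of the same host crop
                same = same_cluster_pops[p]
                if same and rng.random() < cfg.migrant_same_cluster_prob:
                    src = same[rng.integers(len(same))]
                else:
                    cross = other_cluster_pops[cluster_of[p]]
                    src = cross[rng.integers(len(cross))]
                statuses.append((p, "migrant", src, None))
            elif in_pair and u < cfg.migrant_rate + pair_rate:
                donors = [q for q in pops if cluster_of[q] == sibling_of[cluster_of[p]]]
                donor = donors[rng.integers(len(donors))]
                statuses.append((p, "admixed", None, donor))
            else:
                statuses.append((p, "resident", None, None))

    # genotype pool demand per population
    demand = {p: 0 for p in pops}
    for home, kind, src, donor in statuses:
        if kind == "resident":
            demand[home] += 1
        elif kind == "migrant":
            demand[src] += 1
        else:
            demand[home] += 1
            demand[donor] += 1
    for p in pops:
        demand[p] = max(demand[p], 1)

    events, ne = _fixture_scenario(cfg, pops, cluster_of)
    ghost_demes = [d for d in ne if d not in demand]
    spec = ScenarioSpec(
        name="study_fixture",
        demes=tuple([(p, demand[p]) for p in pops] + [(g, 0) for g in ghost_demes]),
        events=tuple((dv, sr, f"t@{dv}") for dv, sr, _ in events),
        param_priors=tuple(
            [(f"N_{d}", (v * 0.999999, v * 1.000001)) for d, v in ne.items()]
            + [(f"t@{dv}", (tv * 0.999999, tv * 1.000001)) for dv, _, tv in events]
        ),
    )
    fixed_values = {f"N_{d}": float(v) for d, v in ne.items()}
    fixed_values.update({f"t@{dv}": float(tv) for dv, _, tv in events})
    params = ParamVector(
        values=tuple(sorted(fixed_values.items())),
        locus_rates=tuple([cfg.mu] * cfg.n_loci),
        p_gsm=cfg.p_gsm,
        selfing=cfg.selfing,
    )
    mut = MutationModel(
        mean_rate_bounds=(cfg.mu, cfg.mu), p_bounds=(cfg.p_gsm, cfg.p_gsm), n_states=cfg.n_states
    )
    pool_ds = simulate_dataset(
        spec, params, sample_sizes=demand, loci=default_loci(cfg.n_loci, n_states=cfg.n_states),
        seed=rng, mutation=mut, id_prefix="pool",
    )
    pool_idx = pool_ds.populations
    cursor = {p: 0 for p in pops}

    def take_genotype(p: str) -> np.ndarray:
        i = pool_idx[p][cursor[p]]
        cursor[p] += 1
        return pool_ds.calls[i]

    # coordinates: clusters occupy loose regional blocks in a European box
    pop_coord: dict[str, tuple[float, float]] = {}
    for ci, host in enumerate(hosts):
        lat0 = 42.0 + 2.0 * ci
        lon0 = -2.0 + 4.0 * ci
        for p in pops:
            if cluster_of[p] == host:
                pop_coord[p] = (
                    lat0 + rng.uniform(0, 3.0),
                    lon0 + rng.uniform(0, 5.0),
                )

    n_total = len(statuses)
    calls = np.empty((n_total, cfg.n_loci, 2), dtype=np.int64)
    samples: list[SampleMeta] = []
    rows = []
    for i, (home, kind, src, donor) in enumerate(statuses):
        if kind == "resident":
            calls[i] = take_genotype(home)
        elif kind == "migrant":
            calls[i] = take_genotype(src)
        else:
            g_home = take_genotype(home)
            g_donor = take_genotype(donor)
            # admixed = descendant of a sibling-cluster F1 after g selfing
            # generations: residual heterozygosity 0.5^g per locus, the rest
            # a homozygous mosaic.  Mirrors an admixed selfing lineage
            # rather than a fresh outcross, which would be implausibly
            # heterozygous for this mating system.
            g_self = cfg.admixed_selfing_generations
            pick_h = rng.integers(2, size=cfg.n_loci)
            pick_d = rng.integers(2, size=cfg.n_loci)
            h_allele = g_home[np.arange(cfg.n_loci), pick_h]
            d_allele = g_donor[np.arange(cfg.n_loci), pick_d]
            still_het = rng.random(cfg.n_loci) < 0.5**g_self
            fixed_home = rng.random(cfg.n_loci) < 0.5
            a0 = np.where(still_het | fixed_home, h_allele, d_allele)
            a1 = np.where(still_het, d_allele, a0)
            calls[i, :, 0] = a0
            calls[i, :, 1] = a1
        lat, lon = pop_coord[home]
        samples.append(
            SampleMeta(
                individual_id=f"ind{i + 1:04d}",
                population_id=home,
                host_crop=cluster_of[home],
                country="synthetic",
                latitude=lat,
                longitude=lon,
            )
        )
        rows.append(
            {
                "individual_id": f"ind{i + 1:04d}",
                "population_id": home,
                "cluster": cluster_of[home],
                "is_migrant": kind == "migrant",
                "source_population": src or "",
                "is_admixed": kind == "admixed",
                "donor_population": donor or "",
            }
        )
    ds = GenotypeDataset(loci=pool_ds.loci, samples=samples, calls=calls)
    return StudyFixture(dataset=ds, truth=pd.DataFrame(rows), config=cfg)
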