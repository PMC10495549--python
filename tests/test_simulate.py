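"""Scenario builders, prior draws, and coalescent engine behaviour."""

import numpy as np
import pytest

from broompop import popstats
from broompop.simulate import (
    FixtureConfig,
    MutationModel,
    ParamVector,
    ScenarioSpec,
    build_ghost_scenario,
    build_six_scenarios,
    build_toy_scenarios,
    draw_params,
    make_study_fixture,
    simulate_dataset,
    default_loci,
    _reflect,
    _simulate_genealogy,
)


def one_deme(n, ne):
    return ScenarioSpec(
        name="one",
        demes=((("A", n)),),
        events=(),
        param_priors=(("N_A", (ne * 0.999999, ne * 1.000001)),),
    )


FIXED_MUT = MutationModel(mean_rate_bounds=(5e-4, 5e-4), rate_shape=1e9, p_bounds=(0.2, 0.2))


class TestScenarioSpec:
    def test_events_must_form_rooted_tree(self):
        with pytest.raises(ValueError, match="rooted tree"):
            ScenarioSpec(
                name="bad",
                demes=(("A", 5), ("B", 5)),
                events=(),
                param_priors=(("N_A", (10, 100)), ("N_B", (10, 100))),
            )

    def test_missing_ne_prior_rejected(self):
        with pytest.raises(ValueError, match="N_B"):
            ScenarioSpec(
                name="bad",
                demes=(("A", 5), ("B", 5)),
                events=(("B", "A", "t"),),
                param_priors=(("N_A", (10, 100)), ("t", (1, 10))),
            )

    def test_json_round_trip(self):
        spec = build_ghost_scenario()
        assert ScenarioSpec.from_json(spec.to_json()) == spec


class TestDrawParams:
    def test_draws_respect_bounds(self):
        spec = build_ghost_scenario()
        rng = np.random.default_rng(0)
        lo_hi = spec.priors
        for _ in range(500):
            pv = draw_params(spec, rng)
            for name, val in pv.values:
                lo, hi = lo_hi[name]
                assert lo <= val <= hi

    def test_constraints_always_hold(self):
        spec = build_ghost_scenario()
        rng = np.random.default_rng(1)
        for _ in range(500):
            pv = draw_params(spec, rng)
            d = pv.as_dict()
            assert d["t_ancient"] > d["t_TB_HP"]
            assert d["t_ancient"] > d["t_OR_ghost"]

    def test_same_seed_identical_vectors(self):
        spec = build_ghost_scenario()
        assert draw_params(spec, 77) == draw_params(spec, 77)

    def test_unsatisfiable_constraints_raise(self):
        spec = ScenarioSpec(
            name="impossible",
            demes=(("A", 2), ("B", 2)),
            events=(("B", "A", "t1"),),
            param_priors=(
                ("N_A", (10, 20)),
                ("N_B", (10, 20)),
                ("t1", (1, 2)),
                ("t2", (5, 6)),
            ),
            constraints=(("t1", "t2"),),
        )
        with pytest.raises(RuntimeError, match="constraints"):
            draw_params(spec, 0, max_tries=50)


class TestScenarioBuilders:
    def test_six_scenarios_count_and_distinct(self):
        specs = build_six_scenarios()
        assert len(specs) == 6
        assert len({s.name for s in specs}) == 6
        topologies = {(s.events[0][0], s.events[0][1]) for s in specs}
        assert len(topologies) == 6  # (derived, parent) pairs all distinct

    def test_six_scenarios_time_structure(self):
        for s in build_six_scenarios():
            times = [t for t in s.priors if t.startswith("t_")]
            assert sorted(times) == ["t_ancient", "t_recent"]
            assert ("t_ancient", "t_recent") in s.constraints
            assert s.priors["t_ancient"] == (100.0, 100_000.0)
            assert s.priors["t_recent"] == (10.0, 10_000.0)

    def test_best_supported_topology_present(self):
        # most ancient split between OR and HP ancestors, TB derived from HP
        names = {s.name for s in build_six_scenarios()}
        assert "ancient_OR_HP__TB_from_HP" in names

    def test_ghost_scenario_structure(self):
        spec = build_ghost_scenario()
        sizes = dict(spec.demes)
        assert sizes["ghost"] == 0
        assert spec.priors["t_ancient"] == (1000.0, 50_000.0)
        assert spec.priors["t_TB_HP"] == (10.0, 5000.0)
        assert spec.priors["t_OR_ghost"] == (10.0, 1000.0)
        for d in ("OR", "TB", "HP", "ghost"):
            assert spec.priors[f"N_{d}"] == (10.0, 1000.0)

    def test_ghost_samples_exclude_ghost_deme(self):
        spec = build_ghost_scenario()
        pv = draw_params(spec, 3)
        ds = simulate_dataset(spec, pv, {"OR": 4, "TB": 4, "HP": 4}, seed=3)
        assert sorted(ds.population_ids) == ["HP", "OR", "TB"]

    def test_toy_scenarios_bottleneck_derived_deme(self):
        for s in build_toy_scenarios():
            derived = s.events[0][0]
            assert s.priors[f"N_{derived}"] == (20.0, 60.0)


class TestEngine:
    def test_same_seed_identical_dataset(self):
        spec = build_ghost_scenario()
        pv = draw_params(spec, 5)
        a = simulate_dataset(spec, pv, {"OR": 5, "TB": 5, "HP": 5}, seed=11)
        b = simulate_dataset(spec, pv, {"OR": 5, "TB": 5, "HP": 5}, seed=11)
        assert a == b

    def test_zero_ne_rejected(self):
        with pytest.raises(ValueError):
            ParamVector(values=(("N_A", 0.0),), locus_rates=(1e-4,), p_gsm=0.0)

    def test_alleles_respect_locus_range(self):
        spec = one_deme(10, 100)
        pv = draw_params(spec, 9, mutation=FIXED_MUT)
        loci = default_loci(10)
        ds = simulate_dataset(spec, pv, {"A": 10}, loci=loci, seed=9, mutation=FIXED_MUT)
        for j, locus in enumerate(loci):
            col = ds.calls[:, j, :]
            assert col.min() >= locus.allele_range[0]
            assert col.max() <= locus.allele_range[1]

    def test_reflection_stays_in_bounds(self):
        vals = _reflect(np.arange(-100, 140), 40)
        assert vals.min() >= 0 and vals.max() <= 39

    def test_mean_pairwise_tmrca_is_2n(self):
        rng = np.random.default_rng(21)
        n = 100.0
        times = [
            _simulate_genealogy(rng, {"A": 2}, {"A": n}, [])[1][0] for _ in range(4000)
        ]
        est = np.mean(times)
        se = np.std(times) / np.sqrt(len(times))
        assert abs(est - 2 * n) < 4 * se

    def test_theta_nondecreasing_in_divergence_time(self):
        # 3-point grid of divergence times; mean pairwise theta must be ordered
        mut = FIXED_MUT
        means = []
        for t in (10.0, 500.0, 5000.0):
            spec = ScenarioSpec(
                name=f"t{t}",
                demes=(("A", 10), ("B", 10)),
                events=(("B", "A", "td"),),
                param_priors=(
                    ("N_A", (100.0, 100.001)),
                    ("N_B", (100.0, 100.001)),
                    ("td", (t, t * 1.000001)),
                ),
            )
            rng = np.random.default_rng(int(t))
            thetas = []
            for _ in range(60):
                pv = draw_params(spec, rng, n_loci=5, mutation=mut)
                ds = simulate_dataset(spec, pv, loci=default_loci(5), seed=rng, mutation=mut)
                comp = popstats.wc_components(ds).sum(axis=0)
                thetas.append(comp[0] / comp.sum())
            means.append(np.mean(thetas))
        assert means[0] < means[1] < means[2]


class TestStudyFixture:
    def test_truth_bookkeeping_matches_config(self, study_fixture):
        truth = study_fixture.truth
        cfg = study_fixture.config
        n = len(truth)
        assert n == cfg.n_clusters * cfg.pops_per_cluster * cfg.n_per_pop
        # binomial 3-sigma bands around the planted rates
        m = truth.is_migrant.mean()
        assert abs(m - cfg.migrant_rate) < 3 * np.sqrt(cfg.migrant_rate * 0.91 / n)
        a = truth.is_admixed.mean()
        assert abs(a - cfg.admixture_rate) < 3 * np.sqrt(cfg.admixture_rate * 0.97 / n)
        # migrants carry a source, admixed carry a donor
        assert (truth.loc[truth.is_migrant, "source_population"] != "").all()
        assert (truth.loc[truth.is_admixed, "donor_population"] != "").all()

    def test_fixture_is_deterministic(self):
        cfg = FixtureConfig(n_clusters=3, pops_per_cluster=2, n_per_pop=5)
        a = make_study_fixture(cfg, seed=3)
        b = make_study_fixture(cfg, seed=3)
        assert a.dataset == b.dataset
        assert a.truth.equals(b.truth)

    def test_fixture_shape(self, study_fixture):
        ds = study_fixture.dataset
        assert ds.n_loci == 10
        assert len(ds.population_ids) == 75
        hosts = set(ds.host_of_population.values())
        assert len(hosts) == 5
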