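"""Summary statistics, training tables, LDA axes, forest choice/estimation."""

import numpy as np
import pandas as pd
import pytest

from broompop import abc_rf
from broompop.abc_rf import (
    TrainingSet,
    build_training_set,
    choose_scenario,
    compute_sumstats,
    estimate_params,
    lda_axes,
    prior_scenario_check,
)
from broompop.simulate import (
    MutationModel,
    ScenarioSpec,
    default_loci,
    draw_params,
    simulate_dataset,
)

from conftest import make_dataset


def toy_training(n=120, seed=0, k_classes=2, informative=True):
    """Synthetic training table where one stat carries the class signal."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([f"S{i}" for i in range(k_classes)], n // k_classes)
    x = rng.normal(size=(n, 4))
    if informative:
        x[:, 0] += np.repeat(np.arange(k_classes) * 6.0, n // k_classes)
    stats = pd.DataFrame(x, columns=[f"st{i}" for i in range(4)])
    params = pd.DataFrame({"t": rng.uniform(10, 100, size=n)})
    return TrainingSet(
        stats=stats, labels=pd.Series(labels), params=params,
        stat_names=list(stats.columns),
    )


class TestSumstats:
    def test_identical_demes_no_differentiation(self):
        # identical allele-frequency demes: theta is only unbiased around 0,
        # so with a decent sample size it must sit near 0 (slightly negative)
        block = [[100, 100], [102, 102], [100, 102], [104, 104]] * 10
        ds = make_dataset(block * 2, ["A"] * 40 + ["B"] * 40)
        s = compute_sumstats(ds)
        assert abs(s["theta_A_B"]) < 0.05
        assert s["das_A_B"] == pytest.approx(0.0, abs=1e-12)
        assert s["dmu2_A_B"] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_dataset_conventions(self):
        ds = make_dataset([[100, 100]] * 8, ["A"] * 4 + ["B"] * 4)
        s = compute_sumstats(ds)
        assert s["na_A"] == 1 and s["he_A"] == 0 and s["vas_A"] == 0

    def test_dmu2_matches_hand_formula(self):
        # motif 2: repeats A = {50,50,52,52} mean 51; B = {54,56} mean 55
        calls = [[100, 100], [104, 104], [108, 108], [112, 112]]
        ds = make_dataset(calls, ["A", "A", "B", "B"])
        s = compute_sumstats(ds)
        mean_a = (50 + 52) / 2
        mean_b = (54 + 56) / 2
        assert s["dmu2_A_B"] == pytest.approx((mean_a - mean_b) ** 2)

    def test_deme_mapping_and_order_fixed(self, small_fixture):
        ds = small_fixture.dataset
        hosts = ds.host_of_population
        s = compute_sumstats(ds, demes=hosts)
        demes = sorted(set(hosts.values()))
        expect_names = [f"{p}_{d}" for d in demes for p in ("na", "he", "vas", "gw")]
        assert [n for n in s.index if n.split("_")[0] in ("na", "he", "vas", "gw")] \
            == sorted(expect_names, key=expect_names.index)

    def test_small_deme_rejected(self):
        ds = make_dataset([[100, 100]] * 3, ["A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_sumstats(ds)


class TestTrainingSet:
    @pytest.fixture(scope="class")
    def two_toy_scenarios(self):
        mk = lambda name, t: ScenarioSpec(
            name=name,
            demes=(("A", 10), ("B", 10)),
            events=(("B", "A", "t"),),
            param_priors=(("N_A", (50.0, 200.0)), ("N_B", (50.0, 200.0)), ("t", t)),
        )
        return [mk("recent", (10.0, 50.0)), mk("deep", (3000.0, 9000.0))]

    def test_rows_balanced_and_labelled(self, two_toy_scenarios):
        ts = build_training_set(two_toy_scenarios, n_per_scenario=15, seed=1,
                                loci=default_loci(3))
        assert len(ts.stats) == 30
        assert (ts.labels.value_counts() == 15).all()
        assert not ts.stats.isna().any().any()

    def test_same_seed_byte_identical_tsv(self, tmp_path, two_toy_scenarios):
        a = build_training_set(two_toy_scenarios, n_per_scenario=8, seed=4,
                               loci=default_loci(3))
        b = build_training_set(two_toy_scenarios, n_per_scenario=8, seed=4,
                               loci=default_loci(3))
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.write_tsv(pa)
        b.write_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_divergence_time_shifts_theta(self, two_toy_scenarios):
        ts = build_training_set(two_toy_scenarios, n_per_scenario=25, seed=2,
                                loci=default_loci(3))
        theta = ts.stats["theta_A_B"]
        assert theta[ts.labels == "deep"].mean() > theta[ts.labels == "recent"].mean()


class TestLDAAxes:
    def test_axis_count_capped_at_k_minus_one(self):
        ts = toy_training(k_classes=2)
        aug, _ = lda_axes(ts, n_axes=3)
        assert "LD1" in aug.stats.columns and "LD2" not in aug.stats.columns

    def test_base_stats_unchanged(self):
        ts = toy_training()
        aug, _ = lda_axes(ts, n_axes=1)
        pd.testing.assert_frame_equal(aug.stats[ts.stat_names], ts.stats)

    def test_separable_classes_fully_separated_on_axis(self):
        ts = toy_training(informative=True)
        aug, _ = lda_axes(ts, n_axes=1)
        a = aug.stats.loc[(ts.labels == "S0").values, "LD1"]
        b = aug.stats.loc[(ts.labels == "S1").values, "LD1"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            max(a.max(), b.max()) > min(a.min(), b.min())
        assert (a.mean() - b.mean()) ** 2 > 9

    def test_observed_projection_added(self):
        ts = toy_training()
        obs = ts.stats.iloc[0]
        _, obs_aug = lda_axes(ts, n_axes=1, observed=obs)
        assert "LD1" in obs_aug.index


class TestChooseScenario:
    def test_separable_classes_unanimous_votes(self):
        ts = toy_training(n=200, informative=True)
        obs = ts.stats.iloc[5]  # class S0 territory
        res = choose_scenario(ts, obs, n_trees=100, n_replicates=3, seed=1)
        assert res.selected == "S0"
        assert res.votes["S0"] > 0.95
        assert res.posterior > 0.9
        assert res.global_error < 0.05
        assert np.allclose(res.votes_by_replicate.sum(axis=1), 1.0)

    def test_uninformative_stats_split_votes(self):
        ts = toy_training(n=200, informative=False)
        obs = ts.stats.iloc[0]
        res = choose_scenario(ts, obs, n_trees=100, n_replicates=3, seed=2)
        assert 0.2 < res.votes["S0"] < 0.8
        assert res.global_error > 0.3

    def test_mismatched_observed_names_rejected(self):
        ts = toy_training()
        with pytest.raises(ValueError, match="lacks statistics"):
            choose_scenario(ts, pd.Series({"bogus": 1.0}), n_trees=10, n_replicates=1)


class TestEstimateParams:
    def test_noise_free_stat_recovers_parameter(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(100, 1000, size=300)
        stats = pd.DataFrame({"s1": t + rng.normal(0, 1, 300), "s2": rng.normal(size=300)})
        ts = TrainingSet(
            stats=stats,
            labels=pd.Series(["S"] * 300),
            params=pd.DataFrame({"t": t}),
            stat_names=["s1", "s2"],
        )
        obs = pd.Series({"s1": 500.0, "s2": 0.0})
        est = estimate_params(ts, obs, n_trees=200, seed=4)
        row = est.table.loc["t"]
        assert row["median"] == pytest.approx(500, rel=0.1)
        assert row["q2.5"] <= row["median"] <= row["q97.5"]
        assert row["global_nmae"] < 0.1

    def test_constant_parameter_rejected(self):
        ts = toy_training()
        ts.params["t"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            estimate_params(ts.subset("S0"), ts.stats.iloc[0], n_trees=10)

    def test_multi_scenario_table_rejected(self):
        ts = toy_training()
        with pytest.raises(ValueError, match="single-scenario"):
            estimate_params(ts, ts.stats.iloc[0], n_trees=10)

    def test_reproducible_under_seed(self):
        ts = toy_training().subset("S0")
        obs = ts.stats.iloc[0]
        a = estimate_params(ts, obs, n_trees=50, seed=9)
        b = estimate_params(ts, obs, n_trees=50, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestPriorCheck:
    @pytest.fixture(scope="class")
    def spec(self):
        return ScenarioSpec(
            name="chk",
            demes=(("A", 8), ("B", 8)),
            events=(("B", "A", "t"),),
            param_priors=(("N_A", (50.0, 300.0)), ("N_B", (50.0, 300.0)), ("t", (10.0, 2000.0))),
        )

    def test_self_simulation_quantiles_interior(self, spec):
        pv = draw_params(spec, 8, n_loci=3)
        obs_ds = simulate_dataset(spec, pv, loci=default_loci(3), seed=8)
        obs = compute_sumstats(obs_ds)
        table = prior_scenario_check(spec, obs, n_sim=80, seed=9, loci=default_loci(3))
        assert ((table["quantile"] > 0.0) & (table["quantile"] < 1.0)).all()

    def test_forced_outlier_flagged(self, spec):
        pv = draw_params(spec, 10, n_loci=3)
        obs_ds = simulate_dataset(spec, pv, loci=default_loci(3), seed=10)
        obs = compute_sumstats(obs_ds)
        obs["he_A"] = 5.0  # impossible heterozygosity
        table = prior_scenario_check(spec, obs, n_sim=60, seed=11, loci=default_loci(3))
        assert table.loc["he_A", "flagged"]
        assert table.loc["he_A", "quantile"] == 1.0
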