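"""Diversity and differentiation estimators against hand-rolled oracles."""

import numpy as np
import pytest

from broompop.geno_io import MISSING
from broompop.popstats import (
    DistMatrix,
    amova_nested,
    diversity_by_population,
    great_circle_matrix,
    jost_d,
    jost_d_per_locus,
    mantel_test,
    pairwise_theta,
    wc_components,
    wc_fstats,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracles (straightforward loop implementations)
# ---------------------------------------------------------------------------

def wc_oracle(ds):
    """Weir-Cockerham variance components via direct per-allele loops."""
    pops = ds.populations
    labels = list(pops)
    A = B = C = 0.0
    for j in range(ds.n_loci):
        col = ds.calls[:, j, :]
        alleles = sorted(set(col[col != MISSING].tolist()))
        ns, ps, hs = [], {}, {}
        for p in labels:
            sub = col[pops[p]]
            sub = sub[sub[:, 0] != MISSING]
            ns.append(len(sub))
            for a in alleles:
                ps.setdefault(a, []).append(
                    (sub == a).sum() / (2 * len(sub)) if len(sub) else 0.0
                )
                hs.setdefault(a, []).append(
                    sum(1 for g in sub if a in g and g[0] != g[1])
                )
        ns = np.array(ns, float)
        if (ns == 0).any() or len(alleles) < 2:
            continue
        r = len(labels)
        nbar = ns.mean()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        for a in alleles:
            p_i = np.array(ps[a])
            pbar = (ns * p_i).sum() / ns.sum()
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = sum(hs[a]) / ns.sum()
            a_c = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b_c = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            A, B, C = A + a_c, B + b_c, C + hbar / 2
    return A, B, C


def jost_oracle_locus(ds, j):
    """Nei-Chesser unbiased D at locus j, direct formula."""
    pops = ds.populations
    tabs, ns = [], []
    col = ds.calls[:, j, :]
    alleles = sorted(set(col[col != MISSING].tolist()))
    for p, idx in pops.items():
        sub = col[idx]
        sub = sub[sub[:, 0] != MISSING]
        if not len(sub):
            continue
        tabs.append([np.count_nonzero(sub == a) for a in alleles])
        ns.append(len(sub))
    k = len(tabs)
    freqs = [np.array(t) / sum(t) for t in tabs]
    hs = 1 - np.mean([(f**2).sum() for f in freqs])
    pbar = np.mean(freqs, axis=0)
    ht = 1 - (pbar**2).sum()
    nh = k / sum(1.0 / n for n in ns)
    hs_est = 2 * nh / (2 * nh - 1) * hs
    ht_est = ht + hs_est / (2 * nh * k)
    return (k / (k - 1)) * (ht_est - hs_est) / (1 - hs_est)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_hand_worked_example(self):
        # one locus: 18 copies of A, 2 of B over 10 diploids
        calls = [[100, 100]] * 8 + [[100, 102]] * 2
        t = diversity_by_population(make_dataset(calls, ["P"] * 10)).table
        assert t.Ne_alleles.iloc[0] == pytest.approx(1 / 0.82)
        assert t.uHe.iloc[0] == pytest.approx((20 / 19) * 0.18)
        assert t.Ho.iloc[0] == pytest.approx(0.2)

    def test_monomorphic_population(self):
        t = diversity_by_population(make_dataset([[100, 100]] * 6, ["P"] * 6)).table
        assert t.Na.iloc[0] == 1 and t.Ne_alleles.iloc[0] == 1 and t.uHe.iloc[0] == 0

    def test_missing_calls_excluded_per_locus(self):
        calls = np.array([[[100, 102]], [[MISSING, MISSING]], [[100, 100]]])
        t = diversity_by_population(make_dataset(calls, ["P"] * 3)).table
        # freqs over 2 typed individuals: A=3/4, B=1/4
        assert t.Ne_alleles.iloc[0] == pytest.approx(1 / (0.75**2 + 0.25**2))


class TestWCFstats:
    def test_matches_component_oracle_exactly(self, random_small_ds):
        comp = wc_components(random_small_ds).sum(axis=0)
        oracle = wc_oracle(random_small_ds)
        assert np.allclose(comp, oracle, atol=1e-10)

    def test_complete_fixation_theta_one(self, tiny_two_pop):
        assert wc_fstats(tiny_two_pop, n_boot=19).theta == pytest.approx(1.0)

    def test_all_heterozygous_f_is_minus_one(self):
        ds = make_dataset([[100, 102]] * 16, ["A"] * 8 + ["B"] * 8)
        assert wc_fstats(ds, n_boot=19).f_is == pytest.approx(-1.0)

    def test_bootstrap_ci_brackets_point_estimate(self, random_small_ds):
        res = wc_fstats(random_small_ds, n_boot=199, seed=1)
        assert res.theta_ci[0] <= res.theta <= res.theta_ci[1]

    def test_bootstrap_reproducible(self, random_small_ds):
        a = wc_fstats(random_small_ds, n_boot=99, seed=5)
        b = wc_fstats(random_small_ds, n_boot=99, seed=5)
        assert a.theta_ci == b.theta_ci and a.f_is_ci == b.f_is_ci

    def test_single_polymorphic_locus_flagged_degenerate(self):
        calls = np.full((12, 2, 2), 100)
        calls[6:, 0, :] = 102  # locus 0 polymorphic, locus 1 monomorphic
        ds = make_dataset(calls, ["A"] * 6 + ["B"] * 6)
        with pytest.warns(UserWarning, match="degenerate"):
            res = wc_fstats(ds, n_boot=19)
        assert res.degenerate_ci


class TestJostD:
    def test_fixed_populations_d_one(self, tiny_two_pop):
        assert jost_d(tiny_two_pop, n_boot=19)["D"] == pytest.approx(1.0)

    def test_identical_frequencies_d_zero(self):
        block = [[100, 100], [102, 102], [100, 102]]
        ds = make_dataset(block * 4, ["A"] * 6 + ["B"] * 6)
        assert jost_d(ds, n_boot=19)["D"] == pytest.approx(0.0, abs=1e-12)

    def test_per_locus_matches_formula_oracle(self, random_small_ds):
        ours = jost_d_per_locus(random_small_ds)
        for j in range(random_small_ds.n_loci):
            assert ours[j] == pytest.approx(jost_oracle_locus(random_small_ds, j), abs=1e-10)

    def test_per_stratum_computed_for_groups(self, small_fixture):
        ds = small_fixture.dataset
        res = jost_d(ds, n_boot=9, groups=ds.host_of_population)
        assert set(res["per_stratum"]) == set(ds.host_of_population.values())


class TestAmova:
    def test_variance_concentrates_among_groups_when_groups_fixed(self):
        calls = [[100, 100]] * 10 + [[104, 104]] * 10
        pops = ["A1"] * 5 + ["A2"] * 5 + ["B1"] * 5 + ["B2"] * 5
        ds = make_dataset(calls, pops)
        groups = {"A1": "G1", "A2": "G1", "B1": "G2", "B2": "G2"}
        res = amova_nested(ds, groups, n_boot=19)
        comp = res.table["variance_component"]
        assert comp["among_groups"] / comp.sum() > 0.95

    def test_identical_populations_no_positive_structure(self):
        # exactly duplicated populations: the among sums of squares are zero,
        # so the unbiased among components are non-positive (reported as
        # estimated, not truncated) and all the variance sits within
        rng = np.random.default_rng(0)
        block = rng.choice([100, 102, 104], size=(6, 2, 2))
        calls = np.concatenate([block] * 4)
        pops = sum([[f"P{i}"] * 6 for i in range(4)], [])
        groups = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
        res = amova_nested(make_dataset(calls, pops), groups, n_boot=19)
        comp = res.table["variance_component"]
        assert comp["among_groups"] <= 1e-10
        assert comp["among_populations_within_groups"] <= 1e-10
        assert comp["within_populations"] > 0
        assert res.phi_ct <= 0 and res.phi_sc <= 0

    def test_components_sum_to_total_variance_decomposition(self, random_small_ds):
        ds = random_small_ds
        groups = {"A": "G1", "B": "G2"}
        # with one population per group the among-population stratum pools;
        # use a 4-population layout instead
        calls = ds.calls
        pops = ["A"] * 5 + ["B"] * 4 + ["C"] * 5 + ["D"] * 4
        ds4 = make_dataset(calls, pops)
        res = amova_nested(
            ds4, {"A": "G1", "B": "G1", "C": "G2", "D": "G2"}, n_boot=19
        )
        # oracle: total SS per allele equals sum of stratum SS (conservation)
        t = res.table
        assert np.isfinite(t["variance_component"]).all()
        assert t.loc["within_populations", "df"] == ds4.n_individuals - 4

    def test_singleton_group_pooled_with_warning(self):
        calls = np.full((9, 1, 2), 100)
        calls[0, 0] = (102, 102)
        ds = make_dataset(calls, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        with pytest.warns(UserWarning, match="pooled"):
            amova_nested(ds, {"A": "G1", "B": "G1", "C": "G2"}, n_boot=9)


class TestGeography:
    def test_identical_points_zero(self):
        m = great_circle_matrix({"a": (45.0, 5.0), "b": (45.0, 5.0)})
        assert m.values[0, 1] == pytest.approx(0.0)

    def test_antipodal_points(self):
        m = great_circle_matrix({"a": (0.0, 0.0), "b": (0.0, 180.0)})
        assert m.values[0, 1] == pytest.approx(np.pi * 6371.0, abs=0.1)

    def test_dijon_thessaloniki_against_hand_haversine(self):
        # independent evaluation of the haversine formula
        lat1, lon1, lat2, lon2 = map(np.radians, (47.32, 5.04, 40.64, 22.94))
        h = (
            np.sin((lat2 - lat1) / 2) ** 2
            + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
        )
        expect = 2 * 6371.0 * np.arcsin(np.sqrt(h))
        m = great_circle_matrix({"dijon": (47.32, 5.04), "thess": (40.64, 22.94)})
        assert m.values[0, 1] == pytest.approx(expect, abs=0.1)

    def test_missing_coordinates_excluded(self):
        with pytest.warns(UserWarning, match="missing coordinates"):
            m = great_circle_matrix({"a": (45.0, 5.0), "b": (None, None), "c": (46.0, 6.0)})
        assert m.labels == ("a", "c")


class TestMantel:
    def _mat(self, vals, labels=("a", "b", "c", "d")):
        return DistMatrix(labels, np.asarray(vals, float))

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        v = rng.random((4, 4))
        v = np.triu(v, 1)
        v = v + v.T
        d = self._mat(v)
        r, p = mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        base = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
        d1 = self._mat(base)
        d2 = self._mat(2 * base + 3 * (1 - np.eye(4)))
        r, _ = mantel_test(d1, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        d1 = self._mat(1 - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d1, d1, n_perm=9)

    def test_null_type_one_error_calibrated(self):
        # independent random matrices: rejection rate at alpha=.05 must be ~5%
        rng = np.random.default_rng(7)
        n, hits, trials = 10, 0, 1000
        labels = tuple(f"u{i}" for i in range(n))
        for _ in range(trials):
            a = rng.random((n, n))
            b = rng.random((n, n))
            a, b = np.triu(a, 1), np.triu(b, 1)
            d1 = DistMatrix(labels, a + a.T)
            d2 = DistMatrix(labels, b + b.T)
            _, p = mantel_test(d1, d2, n_perm=99, seed=rng)
            hits += p <= 0.05
        assert 0.03 <= hits / trials <= 0.07

    def test_pairwise_theta_symmetry(self, small_fixture):
        ds = small_fixture.dataset.take(range(44))  # 4 pops
        m = pairwise_theta(ds)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)
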