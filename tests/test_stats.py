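"""Permutation tests, BH-FDR and partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glyconnect import stats

from .oracles import bh_adjust_by_hand


def two_groups(n=20):
    return np.array(["control"] * n + ["patient"] * n)


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        obs, p = stats.permutation_test(v, two_groups(10), n_perm=500, rng=0)
        assert obs == 0.0
        assert p == 1.0

    def test_constant_values_p_one(self):
        v = np.full(20, 3.3)
        _, p = stats.permutation_test(v, two_groups(10), n_perm=100, rng=0)
        assert p == 1.0

    def test_shift_invariance_and_label_invariance(self):
        r = np.random.default_rng(4)
        v = r.normal(size=24)
        g = two_groups(12)
        _, p1 = stats.permutation_test(v, g, n_perm=999, rng=1)
        _, p2 = stats.permutation_test(v + 100.0, g, n_perm=999, rng=1)
        assert p1 == p2
        relabeled = np.where(g == "control", "x", "y")
        _, p3 = stats.permutation_test(v, relabeled, n_perm=999, rng=1)
        assert p1 == p3

    def test_obvious_effect_detected(self):
        r = np.random.default_rng(0)
        v = np.r_[r.normal(0, 1, 20), r.normal(3, 1, 20)]
        obs, p = stats.permutation_test(v, two_groups(20), n_perm=2000, rng=2)
        assert obs > 2
        assert p < 0.01

    def test_p_never_zero_and_smoothed(self):
        v = np.r_[np.zeros(5), np.ones(5) * 10]
        _, p = stats.permutation_test(v, two_groups(5), n_perm=200, rng=0)
        assert p >= 1.0 / 201

    def test_power_at_study_effect_size(self):
        """Groups N(0,1) vs N(1.33,1) at n=20/20: the efficiency-sized effect
        is detected with p < 0.001 in the majority of replicates."""
        r = np.random.default_rng(8)
        small_p = 0
        for _ in range(20):
            v = np.r_[r.normal(0, 1, 20), r.normal(1.33, 1, 20)]
            _, p = stats.permutation_test(v, two_groups(20), n_perm=4000, rng=r)
            small_p += p < 0.001
        assert small_p > 10

    def test_null_p_values_approximately_uniform(self):
        """Under the full null, permutation p-values are ~Uniform(0,1)
        (Kolmogorov-Smirnov sanity check over 250 replicates)."""
        r = np.random.default_rng(17)
        ps = []
        for _ in range(250):
            v = r.normal(size=24)
            ps.append(stats.permutation_test(v, two_groups(12), n_perm=400, rng=r)[1])
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.001

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="2 groups"):
            stats.permutation_test(np.arange(4.0), np.array(["a"] * 4))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            stats.permutation_test(
                np.arange(4.0), np.array(["a", "b", "b", "b"])
            )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert stats.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_example_equal_ratios(self):
        q = stats.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.05] * 5)

    def test_all_ones(self):
        np.testing.assert_allclose(stats.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_bh_on_random_inputs(self):
        r = np.random.default_rng(1)
        for _ in range(10):
            p = r.uniform(1e-6, 1, size=r.integers(1, 12))
            np.testing.assert_allclose(stats.bh_fdr(p), bh_adjust_by_hand(p))

    def test_order_invariance(self):
        p = np.array([0.04, 0.001, 0.3, 0.02])
        perm = [2, 0, 3, 1]
        q = stats.bh_fdr(p)
        q_perm = stats.bh_fdr(p[perm])
        np.testing.assert_allclose(q[perm], q_perm)

    def test_empty_and_invalid(self):
        assert stats.bh_fdr([]).size == 0
        with pytest.raises(ValueError):
            stats.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            stats.bh_fdr([1.5])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        r = np.random.default_rng(2)
        x, y = r.normal(size=30), r.normal(size=30)
        rr, pp = stats.partial_correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert rr == pytest.approx(ref_r, rel=1e-10)
        assert pp == pytest.approx(ref_p, rel=1e-6)

    def test_identical_variables_r_one(self):
        r = np.random.default_rng(3)
        x = r.normal(size=25)
        z = r.normal(size=(25, 2))
        rr, _ = stats.partial_correlation(x, x, z)
        assert rr == pytest.approx(1.0)

    def test_known_trivariate_partial(self):
        """x,y,z trivariate normal engineered so the x,y partial correlation
        given z is 0.5 (closed-form from the generating covariance)."""
        rho_xy_target = 0.5
        a = 0.6  # loading of z on both x and y
        # x = a z + e1, y = a z + e2 with corr(e1, e2) = rho_xy_target
        r = np.random.default_rng(10)
        n = 10_000
        z = r.normal(size=n)
        cov = np.array([[1.0, rho_xy_target], [rho_xy_target, 1.0]])
        e = r.multivariate_normal([0, 0], cov, size=n)
        x = a * z + e[:, 0]
        y = a * z + e[:, 1]
        rr, pp = stats.partial_correlation(x, y, z[:, None])
        assert rr == pytest.approx(0.5, abs=0.03)
        assert pp < 1e-10

    def test_affine_invariance(self):
        r = np.random.default_rng(5)
        x, y = r.normal(size=40), r.normal(size=40)
        z = r.normal(size=(40, 2))
        r1, p1 = stats.partial_correlation(x, y, z)
        r2, p2 = stats.partial_correlation(3 * x - 7, -2 * y + 1, 5 * z + 2)
        assert abs(r2) == pytest.approx(abs(r1), rel=1e-10)
        assert p2 == pytest.approx(p1, rel=1e-8)

    def test_rank_deficient_covariates_named(self):
        r = np.random.default_rng(6)
        x, y = r.normal(size=20), r.normal(size=20)
        z = np.column_stack([r.normal(size=20), np.ones(20)])  # col 1 = intercept
        with pytest.raises(ValueError, match="collinear"):
            stats.partial_correlation(x, y, z)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="n > k\\+2"):
            stats.partial_correlation(
                np.arange(5.0), np.arange(5.0), np.ones((5, 3)) * np.arange(3)
            )


class TestAnalyzeCohort:
    @staticmethod
    def toy_tables(seed=0, effect=0.0):
        r = np.random.default_rng(seed)
        n = 12
        ids = [f"s{i:02d}" for i in range(2 * n)]
        groups = ["control"] * n + ["patient"] * n
        met = pd.DataFrame({"subject_id": ids})
        for m in stats.GLOBAL_MEASURES:
            v = r.normal(size=2 * n)
            if m in ("E",):
                v[n:] -= effect
            met[m] = v
        met["n_edges"] = r.integers(40, 60, size=2 * n)
        met["total_strength"] = r.normal(10, 1, size=2 * n)
        rec = pd.DataFrame(
            {
                "subject_id": ids,
                "group": groups,
                "age": r.uniform(50, 60, 2 * n),
                "sex": r.integers(0, 2, 2 * n),
                "hba1c": r.normal(8, 2, 2 * n),
                "fpg": r.normal(7, 2, 2 * n),
            }
        )
        return met, rec

    def test_shapes_and_families(self):
        met, rec = self.toy_tables()
        comps, corrs = stats.analyze_cohort(met, rec, n_perm=200, rng=0)
        assert [c.measure for c in comps] == list(stats.GLOBAL_MEASURES)
        assert len(corrs) == 10  # 5 measures x 2 glucose variables
        assert all(0 < c.p <= 1 and 0 < c.q <= 1 for c in comps)
        assert all(-1 <= c.r <= 1 for c in corrs)
        assert all(c.controlled == tuple(stats.CONTROL_VARS) for c in corrs)

    def test_group_effect_detected_in_right_measure(self):
        met, rec = self.toy_tables(seed=1, effect=3.0)
        comps, _ = stats.analyze_cohort(met, rec, n_perm=2000, rng=1)
        by = {c.measure: c for c in comps}
        assert by["E"].q < 0.05
        assert by["E"].observed_diff < 0

    def test_join_failure_lists_ids(self):
        met, rec = self.toy_tables()
        rec = rec.copy()
        rec.loc[0, "subject_id"] = "zz99"
        with pytest.raises(ValueError, match="zz99"):
            stats.analyze_cohort(met, rec)

    def test_constant_control_column_dropped_with_warning(self):
        met, rec = self.toy_tables(seed=2)
        met["n_edges"] = 50
        with pytest.warns(UserWarning, match="n_edges"):
            _, corrs = stats.analyze_cohort(met, rec, n_perm=100, rng=0)
        assert all("n_edges" not in c.controlled for c in corrs)

    def test_patients_only_correlation_subjects(self):
        met, rec = self.toy_tables(seed=3)
        _, corrs = stats.analyze_cohort(
            met, rec, n_perm=100, rng=0, correlation_subjects="patient"
        )
        assert all(c.n == 12 for c in corrs)

    def test_null_cohort_q_rarely_significant(self):
        """Without any injected effect, significant q-values are rare."""
        n_sig = 0
        n_tests = 0
        for s in range(15):
            met, rec = self.toy_tables(seed=100 + s)
            comps, _ = stats.analyze_cohort(met, rec, n_perm=400, rng=s)
            n_sig += sum(c.q < 0.05 for c in comps)
            n_tests += len(comps)
        assert n_sig <= 0.1 * n_tests
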