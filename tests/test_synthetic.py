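"""Synthetic cohort generator, covariates, calibration and phantom."""

import numpy as np
import pytest
from scipy import stats as sps

from glyconnect import metrics
from glyconnect.diffusion import fit_tensor
from glyconnect.synthetic import (
    PhantomRegion,
    SyntheticCohortConfig,
    TensorPhantomConfig,
    calibrate_shortcut_prob,
    calibrate_weight_scale,
    gen_cohort,
    gen_covariates,
    gen_tensor_phantom,
    records_frame,
    _subject_matrix,
)

from .oracles import efficiency_bruteforce


def small_cfg(**kw):
    defaults = dict(
        n_per_group=4,
        n_nodes=40,
        lattice_degree=6,
        shortcut_prob_control=0.3,
        shortcut_prob_patient=0.05,
        weight_scale_control=1.0,
        weight_scale_patient=1.0,
        seed=0,
    )
    defaults.update(kw)
    return SyntheticCohortConfig(**defaults)


class TestCohortGenerator:
    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError, match="lattice_degree"):
            SyntheticCohortConfig(n_nodes=10, lattice_degree=12)
        with pytest.raises(ValueError, match="even"):
            SyntheticCohortConfig(lattice_degree=7)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SyntheticCohortConfig(shortcut_prob_control=1.5)
        with pytest.raises(ValueError, match="positive"):
            SyntheticCohortConfig(weight_scale_patient=-1.0)

    def test_no_randomness_gives_exact_identical_ring_lattices(self):
        cfg = small_cfg(
            shortcut_prob_control=0.0,
            shortcut_prob_patient=0.0,
            weight_dispersion=0.0,
        )
        mats, _ = gen_cohort(cfg)
        w0 = mats[0].weights
        # exact ring lattice topology
        n, k = cfg.n_nodes, cfg.lattice_degree
        expected = np.zeros((n, n), dtype=bool)
        for off in range(1, k // 2 + 1):
            for i in range(n):
                expected[i, (i + off) % n] = expected[(i + off) % n, i] = True
        np.testing.assert_array_equal(w0 > 0, expected)
        # all subjects identical, uniform weights
        for m in mats:
            np.testing.assert_array_equal(m.weights, w0)
        assert np.unique(w0[w0 > 0]).size == 1

    def test_same_seed_identical_output(self):
        cfg = small_cfg(seed=33)
        m1, r1 = gen_cohort(cfg)
        m2, r2 = gen_cohort(cfg)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.weights, b.weights)
        assert records_frame(r1).equals(records_frame(r2))

    def test_more_shortcuts_higher_efficiency(self):
        """Ensemble-mean efficiency (brute-force oracle) is strictly higher
        in the group with more shortcuts, at equal weight scale."""
        cfg = small_cfg(n_per_group=6, seed=5)
        mats, _ = gen_cohort(cfg)
        e_ctrl = np.mean([efficiency_bruteforce(m.weights) for m in mats[:6]])
        e_pat = np.mean([efficiency_bruteforce(m.weights) for m in mats[6:]])
        assert e_ctrl > e_pat

    def test_records_structure(self):
        cfg = small_cfg(n_per_group=10, seed=2)
        _, recs = gen_cohort(cfg)
        df = records_frame(recs)
        assert len(df) == 20
        assert set(df.group) == {"control", "patient"}
        # sex balanced within group at the study's 9/20 ratio
        assert df[df.group == "control"].sex.sum() == round(10 * 9 / 20)
        assert df.age.between(*cfg.age_range).all()

    def test_edge_filter_exercised(self):
        """Log-normal counts leave some pairs below the 3-streamline rule, so
        per-subject edge counts vary."""
        mats, _ = gen_cohort(SyntheticCohortConfig(n_per_group=5, seed=3))
        n_edges = [(m.weights > 0).sum() // 2 for m in mats]
        full = 144 * 12 // 2
        assert all(e < full for e in n_edges)
        assert len(set(n_edges)) > 1


class TestGenCovariates:
    def test_zero_target_independent(self):
        r = np.random.default_rng(0)
        v = r.normal(size=5000)
        c = gen_covariates(v, 0.0, rng=1)
        assert abs(sps.pearsonr(v, c)[0]) < 0.05

    def test_strong_target_large_n(self):
        r = np.random.default_rng(1)
        v = r.normal(size=10_000)
        c = gen_covariates(v, 0.99, rng=2)
        assert sps.pearsonr(v, c)[0] == pytest.approx(0.99, abs=0.01)

    def test_study_strength_small_n_mean_over_seeds(self):
        """target r = -0.53 at n = 40: mean sample correlation over 200 seeds
        sits at the target."""
        r = np.random.default_rng(3)
        v = r.normal(size=40)
        rs = [
            sps.pearsonr(v, gen_covariates(v, -0.53, rng=s))[0] for s in range(200)
        ]
        assert np.mean(rs) == pytest.approx(-0.53, abs=0.03)

    def test_mean_sd_rescaling(self):
        r = np.random.default_rng(4)
        v = r.normal(size=50)
        c = gen_covariates(v, 0.4, rng=5, mean=8.3, sd=2.5)
        assert c.mean() == pytest.approx(8.3)
        assert c.std() == pytest.approx(2.5)

    def test_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            gen_covariates(np.ones(10), 0.5, rng=0)
        with pytest.raises(ValueError, match="target_r"):
            gen_covariates(np.arange(10.0), 1.0, rng=0)
        with pytest.raises(ValueError, match=">= 3"):
            gen_covariates(np.arange(2.0), 0.5, rng=0)


class TestCalibration:
    def test_weight_scale_identity(self):
        m = _subject_matrix(small_cfg(), "control", np.random.default_rng(0))
        e = metrics.global_efficiency(m.weights)
        assert calibrate_weight_scale(m, e) == pytest.approx(1.0)

    def test_weight_scale_doubles_pipeline_efficiency(self):
        m = _subject_matrix(small_cfg(), "control", np.random.default_rng(1))
        e = metrics.global_efficiency(m.weights)
        s = calibrate_weight_scale(m, 2 * e)
        assert s == pytest.approx(2.0)
        assert metrics.global_efficiency(s * m.weights) == pytest.approx(
            2 * e, rel=1e-12
        )
        # oracle agrees
        assert efficiency_bruteforce(s * m.weights[:12, :12]) == pytest.approx(
            2 * efficiency_bruteforce(m.weights[:12, :12]), rel=1e-9
        )

    def test_weight_scale_to_printed_control_mean(self):
        """A base network with E = 0.5e-3 scaled to the printed control mean
        0.63e-3 needs s = 1.26, and the pipeline measures 0.63e-3 after scaling."""
        m = _subject_matrix(small_cfg(seed=9), "control", np.random.default_rng(9))
        w = m.weights * (0.5e-3 / metrics.global_efficiency(m.weights))
        assert metrics.global_efficiency(w) == pytest.approx(0.5e-3, rel=1e-12)
        m.weights = w
        s = calibrate_weight_scale(m, 0.63e-3)
        assert s == pytest.approx(1.26, rel=1e-9)
        assert metrics.global_efficiency(s * w) == pytest.approx(0.63e-3, rel=1e-9)

    def test_weight_scale_errors(self):
        m = _subject_matrix(small_cfg(), "control", np.random.default_rng(0))
        with pytest.raises(ValueError, match="positive"):
            calibrate_weight_scale(m, -1.0)

    def test_shortcut_prob_extreme_target_is_random_graph(self):
        cfg = small_cfg(n_nodes=40, lattice_degree=6)
        p = calibrate_shortcut_prob(1.0, cfg, n_null=5, n_probe=3, tol=0.05, rng=0)
        assert p > 0.4

    def test_shortcut_prob_monotone_in_target(self):
        cfg = small_cfg(n_nodes=40, lattice_degree=6)
        p_low = calibrate_shortcut_prob(1.05, cfg, n_null=5, n_probe=4, tol=0.03, rng=1)
        p_high = calibrate_shortcut_prob(1.6, cfg, n_null=5, n_probe=4, tol=0.03, rng=1)
        assert p_high < p_low

    def test_unreachable_target_names_range(self):
        cfg = small_cfg(n_nodes=40, lattice_degree=6)
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_shortcut_prob(50.0, cfg, n_null=4, n_probe=2, rng=2)
        with pytest.raises(ValueError, match=">= 1"):
            calibrate_shortcut_prob(0.5, cfg, n_null=4, n_probe=2, rng=2)


class TestTensorPhantom:
    def test_isotropic_noiseless_fa_zero_after_refit(self):
        cfg = TensorPhantomConfig(grid_shape=(4, 4, 4), noise_sd=0.0, seed=0)
        ph = gen_tensor_phantom(cfg)
        from glyconnect.diffusion import tensor_scalars

        fitted = fit_tensor(ph.signals, ph.b_values, ph.b_vectors)
        fa = tensor_scalars(fitted)["FA"].data
        np.testing.assert_allclose(fa, 0.0, atol=1e-9)

    def test_noiseless_refit_recovers_tensor(self):
        bar = PhantomRegion(
            bbox=((0, 3), (0, 4), (0, 4)),
            direction=(0.3, -0.5, 0.8),
            eigvals=(1.5e-3, 0.4e-3, 0.3e-3),
        )
        cfg = TensorPhantomConfig(grid_shape=(6, 4, 4), field_spec=[bar], seed=1)
        ph = gen_tensor_phantom(cfg)
        fitted = fit_tensor(ph.signals, ph.b_values, ph.b_vectors)
        err = np.abs(fitted.data - ph.tensors.data).max()
        scale = np.abs(ph.tensors.data).max()
        assert err / scale < 1e-10

    def test_labels_mark_terminal_regions(self, xbar_phantom):
        ph = gen_tensor_phantom(xbar_phantom)
        assert set(np.unique(ph.labels.data)) == {0, 1, 2}
        assert (ph.labels.data[0:3, 3:7, 3:7] == 1).all()

    def test_negative_eigenvalue_rejected(self):
        bad = PhantomRegion(bbox=((0, 1), (0, 1), (0, 1)), eigvals=(1e-3, -1e-4, 1e-4))
        with pytest.raises(ValueError, match="non-negative"):
            TensorPhantomConfig(grid_shape=(2, 2, 2), field_spec=[bad])

    def test_determinism(self):
        cfg = TensorPhantomConfig(grid_shape=(3, 3, 3), noise_sd=5.0, seed=4)
        a = gen_tensor_phantom(cfg)
        b = gen_tensor_phantom(cfg)
        np.testing.assert_array_equal(a.signals, b.signals)
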