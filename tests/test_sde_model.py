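"""The SDE edge model: g(t), the model curve, fitting, and the sharpness index."""

import numpy as np
import pytest

from effcnr import (
    EdgeProfile,
    SDEParams,
    analytic_differential,
    edge_model,
    effective_contrast,
    fit_edge_model,
    g_of_t,
    make_model_profile,
    model_differential_profile,
    sharpness_index,
)

REF = SDEParams(c0=60.0, sigma=1.0, gamma=2.5, baseline=0.0)


class TestGofT:
    def test_direct_arithmetic_at_t0(self):
        # (ln 1e-13 + 3*50)/sqrt(50)
        assert g_of_t(0.0, REF) == pytest.approx((np.log(1e-13) + 3 * 50) / np.sqrt(50), rel=1e-12)
        assert g_of_t(0.0, REF) == pytest.approx(16.98, abs=0.01)

    def test_zero_at_numerator_root(self):
        t_root = REF.t_total - (-REF.lambda_const) / REF.drift
        assert g_of_t(t_root, REF) == pytest.approx(0.0, abs=1e-10)

    def test_diverges_to_minus_infinity_near_t_total(self):
        assert g_of_t(REF.t_total - 1e-9, REF) < -1e3

    def test_domain_error_at_t_total(self):
        with pytest.raises(ValueError, match="undefined"):
            g_of_t(50.0, REF)
        with pytest.raises(ValueError):
            g_of_t(-0.5, REF)


class TestEdgeModel:
    def test_half_contrast_at_g_root(self):
        t_root = REF.t_total - (-REF.lambda_const) / REF.drift
        assert edge_model(t_root, REF) == pytest.approx(REF.baseline + REF.c0 / 2)

    def test_baseline_limit_near_t_total(self):
        assert edge_model(49.9999, REF) == pytest.approx(REF.baseline, abs=1e-8)

    def test_full_contrast_at_origin(self):
        assert edge_model(0.0, REF) == pytest.approx(REF.baseline + REF.c0, abs=1e-6)

    def test_baseline_shifts_whole_curve(self):
        shifted = SDEParams(c0=60.0, sigma=1.0, gamma=2.5, baseline=-40.0)
        t = np.linspace(0, 49, 25)
        assert edge_model(t, shifted) == pytest.approx(edge_model(t, REF) - 40.0)


class TestDifferentialProfile:
    def test_telescoping_sum(self):
        """Unit-spaced per-pixel differences telescope to Phi(g(0)) - Phi(g(T-1))."""
        from scipy.special import ndtr

        t_int = np.arange(0.0, 49.0)
        d = ndtr(g_of_t(t_int, REF)) - ndtr(g_of_t(t_int + 1.0, REF))
        expected = ndtr(g_of_t(0.0, REF)) - ndtr(g_of_t(49.0, REF))
        assert d.sum() == pytest.approx(expected, rel=1e-12)

    def test_grid_step_defaults_to_dt(self):
        diff = model_differential_profile(REF)
        assert diff[1, 0] - diff[0, 0] == pytest.approx(0.10)
        assert diff[:, 0].max() < REF.t_total - 1.0

    def test_near_step_model_peaks_at_one(self):
        """As sigma -> 0 the edge becomes a step and the peak difference -> 1."""
        steep = SDEParams(c0=1.0, sigma=1e-3, gamma=1.0)
        assert sharpness_index(steep).sharpness_index == pytest.approx(1.0, abs=1e-6)

    def test_analytic_derivative_matches_finite_difference(self):
        """Analytic d Phi(g)/dt vs central differences on the dt grid, rel 1e-6."""
        from conftest import stable_central_difference

        for params in (REF, SDEParams(c0=15.0, sigma=2.0, gamma=0.5, baseline=10.0)):
            t = np.arange(0.1, params.t_total - 1.5, params.dt)
            fd = stable_central_difference(t, params)
            ana = analytic_differential(t, params)
            mask = np.abs(fd) > 1e-6 * np.abs(fd).max()
            rel = np.abs(ana[mask] - fd[mask]) / np.abs(fd[mask])
            assert rel.max() < 1e-6


class TestSharpnessIndex:
    def test_independent_of_contrast_scale(self):
        a = SDEParams(c0=100.0, sigma=1.2, gamma=0.8)
        b = SDEParams(c0=1.0, sigma=1.2, gamma=0.8)
        assert sharpness_index(a).sharpness_index == sharpness_index(b).sharpness_index

    def test_bounded_in_unit_interval(self):
        for sigma in (0.3, 1.0, 3.0):
            res = sharpness_index(SDEParams(c0=60.0, sigma=sigma, gamma=1.0))
            assert 0 < res.sharpness_index <= 1
            assert 0 < res.argmax_t < 50

    def test_decreases_with_diffusion_at_fixed_edge_position(self):
        """Larger sigma (gamma adjusted to hold the half-max position) blurs more."""
        t_half = 20.0
        vals = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            gamma = -SDEParams(1, 1, 0).lambda_const / (50.0 - t_half) - sigma**2 / 2
            vals.append(sharpness_index(SDEParams(60.0, sigma, gamma)).sharpness_index)
        assert np.all(np.diff(vals) < 0)


class TestFitEdgeModel:
    def test_noiseless_recovery(self):
        prof = make_model_profile(REF)
        fit = fit_edge_model(prof)
        assert fit.converged
        assert fit.params.c0 == pytest.approx(REF.c0, rel=0.01)
        assert fit.params.sigma == pytest.approx(REF.sigma, rel=0.05)
        assert fit.params.gamma == pytest.approx(REF.gamma, rel=0.05)
        assert fit.rmse_hu < 1e-6

    def test_noisy_recovery_ten_seed_mean(self):
        prof = make_model_profile(REF)
        errs = []
        for seed in range(10):
            noisy = EdgeProfile(
                prof.radii,
                prof.mean_hu + np.random.default_rng(seed).normal(0, 2, len(prof)),
                prof.n_samples,
            )
            errs.append(abs(fit_edge_model(noisy).params.c0 - REF.c0) / REF.c0)
        assert np.mean(errs) < 0.05

    def test_flat_profile_rejected(self):
        prof = EdgeProfile(np.arange(1, 51), np.full(50, 12.0), np.ones(50, int))
        with pytest.raises(ValueError, match="flat profile"):
            fit_edge_model(prof)

    def test_short_profile_rejected(self):
        prof = EdgeProfile(np.arange(1, 6), np.linspace(60, 0, 5), np.ones(5, int))
        with pytest.raises(ValueError, match=">= 10"):
            fit_edge_model(prof)

    def test_baseline_offset_recovered(self):
        shifted = SDEParams(c0=60.0, sigma=1.0, gamma=2.5, baseline=-35.0)
        fit = fit_edge_model(make_model_profile(shifted))
        assert fit.params.baseline == pytest.approx(-35.0, abs=0.5)
        assert fit.params.c0 == pytest.approx(60.0, rel=0.01)

    def test_ideal_step_profile_has_unit_sharpness(self):
        vals = np.where(np.arange(50) <= 14, 60.0, 0.0)
        prof = EdgeProfile(np.arange(50), vals, np.ones(50, int))
        fit = fit_edge_model(prof)
        assert sharpness_index(fit.params).sharpness_index >= 0.95


class TestEffectiveContrast:
    def test_composition_with_known_index(self):
        fit = fit_edge_model(make_model_profile(REF))
        idx_true = sharpness_index(REF).sharpness_index
        assert effective_contrast(fit) == pytest.approx(REF.c0 * idx_true, rel=0.02)

    def test_non_converged_fit_rejected(self):
        fit = fit_edge_model(make_model_profile(REF))
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            effective_contrast(fit)
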