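"""Moving-average noise curves and the apparent noise index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from effcnr import (
    NoiseCurve,
    SquareROI,
    fit_apparent_noise,
    make_noise_field,
    moving_average_sd,
    noise_curve,
    single_point_apparent_noise,
)
from conftest import brute_force_moving_average_sd


class TestMovingAverageSD:
    def test_constant_roi_gives_zero(self):
        assert moving_average_sd(np.full((10, 10), 37.0), 3) == 0.0

    def test_checkerboard_cancels_at_r2(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
        assert moving_average_sd(board, 2) == pytest.approx(0.0, abs=1e-14)

    def test_r1_is_pixel_sd(self):
        rng = np.random.default_rng(3)
        roi = rng.normal(0, 5, (12, 12))
        assert moving_average_sd(roi, 1) == pytest.approx(roi.std(ddof=1))

    def test_iid_r1_recovers_sd20(self):
        sds = [
            moving_average_sd(np.random.default_rng(s).normal(0, 20, (40, 40)), 1)
            for s in range(10)
        ]
        assert np.mean(sds) == pytest.approx(20, rel=0.05)

    def test_r_larger_than_side_errors(self):
        with pytest.raises(ValueError, match="filter size"):
            moving_average_sd(np.zeros((8, 8)), 9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        roi=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=12).filter(
                lambda s: s[0] == s[1]
            ),
            elements=st.floats(-100, 100),
        ),
        r=st.integers(1, 3),
    )
    def test_matches_bruteforce_enumeration(self, roi, r):
        """Vectorized windows agree with a naive double loop to machine precision."""
        expected = brute_force_moving_average_sd(roi, r)
        assert moving_average_sd(roi, r) == pytest.approx(expected, abs=1e-9, rel=1e-12)


class TestNoiseCurve:
    def test_constant_roi_all_zero(self):
        curve = noise_curve(np.zeros((30, 30)))
        assert np.all(curve.sigma_sd == 0)

    def test_curve_length_matches_requested(self):
        curve = noise_curve(np.random.default_rng(0).normal(size=(25, 25)), r_values=range(1, 8))
        assert list(curve.r) == list(range(1, 8))

    def test_gaussian_curve_nonincreasing_within_tolerance(self):
        roi = np.random.default_rng(11).normal(0, 10, (40, 40))
        curve = noise_curve(roi)
        assert np.all(np.diff(curve.sigma_sd) <= 0.05 * curve.sigma_sd[:-1])

    def test_decreasing_r_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            NoiseCurve(np.array([3, 2, 1]), np.array([1.0, 2.0, 3.0]))


class TestFitApparentNoise:
    def test_exact_inverse_r_law_recovered(self):
        r = np.arange(1, 21)
        curve = NoiseCurve(r, 60.0 / r)
        res = fit_apparent_noise(curve)
        assert res.sigma_apparent == pytest.approx(60.0, rel=1e-12)
        assert res.free_slope == pytest.approx(-1.0, abs=1e-12)
        assert res.residual_rms_log == pytest.approx(0.0, abs=1e-12)
        assert res.n_points == 6

    def test_iid_noise_recovers_pixel_sd(self):
        vals = []
        for seed in range(20):
            roi = np.random.default_rng(seed).normal(0, 30, (40, 40))
            vals.append(fit_apparent_noise(noise_curve(roi)).sigma_apparent)
        assert np.mean(vals) == pytest.approx(30, rel=0.10)

    def test_correlated_noise_exceeds_pixel_sd(self):
        field = make_noise_field((128, 128), sd_hu=10, corr_sigma=2, seed=5)
        roi = SquareROI.centered(field).extract(field)
        res = fit_apparent_noise(noise_curve(roi))
        assert res.sigma_apparent > roi.std(ddof=1)

    def test_zero_sigma_in_range_errors(self):
        curve = NoiseCurve(np.arange(1, 21), np.zeros(20))
        with pytest.raises(ValueError, match="undefined|zero"):
            fit_apparent_noise(curve)

    def test_missing_fit_range_errors(self):
        curve = NoiseCurve(np.arange(1, 5), 10.0 / np.arange(1, 5))
        with pytest.raises(ValueError, match="missing"):
            fit_apparent_noise(curve)


class TestSinglePoint:
    def test_arithmetic(self):
        curve = NoiseCurve(np.arange(1, 21), np.full(20, 2.0))
        assert single_point_apparent_noise(curve, r=7) == pytest.approx(14.0)

    def test_exact_law_gives_sigma_apparent(self):
        r = np.arange(1, 21)
        curve = NoiseCurve(r, 60.0 / r)
        assert single_point_apparent_noise(curve, r=7) == pytest.approx(60.0)

    def test_consistent_with_fit_on_iid_noise(self):
        roi = np.random.default_rng(2).normal(0, 30, (40, 40))
        curve = noise_curve(roi)
        fit = fit_apparent_noise(curve).sigma_apparent
        assert single_point_apparent_noise(curve) == pytest.approx(fit, rel=0.15)

    def test_missing_r_errors(self):
        curve = NoiseCurve(np.arange(1, 5), np.ones(4))
        with pytest.raises(KeyError):
            single_point_apparent_noise(curve, r=7)


class TestSquareROI:
    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="not inside"):
            SquareROI((5, 5), side=40).extract(np.zeros((64, 64)))

    def test_centered_roi_extracts_requested_side(self):
        roi = SquareROI.centered(np.zeros((128, 128)), side=40)
        assert roi.extract(np.zeros((128, 128))).shape == (40, 40)
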