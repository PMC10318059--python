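"""Trace extraction, slope fitting, ratios and leak screening."""

import dataclasses

import numpy as np
import pytest

from gutperm import (
    MovieSpec,
    PermeabilityTrace,
    PortLeak,
    SegmentationParams,
    compute_trace,
    endpoint_ratios,
    fit_slope,
    frame_mfi,
    generate_movie,
    leak_profile,
    summarize_condition,
)
from tests.conftest import small_movie_spec


def ols_oracle(t, y):
    """Closed-form normal equations for the straight-line fit."""
    n = len(t)
    sx, sy = t.sum(), y.sum()
    sxx, sxy = (t * t).sum(), (t * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * t + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1.0 - (resid**2).sum() / ss_tot


def _trace(t, y):
    return PermeabilityTrace("c", "cond", np.asarray(t, float), np.asarray(y, float))


class TestFrameMFI:
    def test_constant_medium(self):
        img = np.full((6, 6), 42.0)
        assert frame_mfi(img, np.ones((6, 6), bool)) == 42.0

    def test_two_pixel_mean(self):
        img = np.array([[10.0, 30.0], [99.0, 99.0]])
        mask = np.array([[True, True], [False, False]])
        assert frame_mfi(img, mask) == 20.0

    def test_matches_per_pixel_sum(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(float)
        mask = rng.random((20, 20)) > 0.5
        expected = sum(img[r, c] for r, c in np.argwhere(mask)) / mask.sum()
        assert frame_mfi(img, mask) == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="no medium"):
            frame_mfi(np.zeros((3, 3)), np.zeros((3, 3), bool))

    def test_invariant_to_tissue_pixels(self, rng):
        img = rng.integers(0, 200, (20, 20)).astype(float)
        mask = rng.random((20, 20)) > 0.5
        altered = img.copy()
        altered[~mask] = 255.0
        assert frame_mfi(img, mask) == frame_mfi(altered, mask)


class TestComputeTrace:
    def test_recovers_generator_ramp_exactly(self):
        # medium ramps linearly; noiseless unquantized phantom
        spec = small_movie_spec(true_slope_per_hour=0.5, duration_hours=8.0)
        stack, truth = generate_movie(spec)
        trace = compute_trace(stack)
        assert np.allclose(trace.raw_mfi, truth.true_medium_mean, atol=1e-9)
        assert np.allclose(trace.normalized_mfi, 1 + 0.5 * trace.times_hours, atol=1e-9)

    def test_normalized_starts_at_one(self):
        stack, _ = generate_movie(small_movie_spec(noise_sigma=2.0, quantize=True))
        trace = compute_trace(stack)
        assert trace.normalized_mfi[0] == 1.0

    def test_constant_medium_trace_is_flat(self):
        stack, _ = generate_movie(small_movie_spec())
        trace = compute_trace(stack)
        assert np.allclose(trace.normalized_mfi, 1.0)

    def test_too_few_frames_rejected(self):
        stack, _ = generate_movie(small_movie_spec(duration_hours=0.25))
        with pytest.raises(ValueError, match="3 frames"):
            compute_trace(stack)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _trace([0, 1, 2], [0.0, 1.0, 2.0])


class TestFitSlope:
    def test_exact_line(self):
        t = np.linspace(0, 8, 9)
        fit = fit_slope(_trace(t, 1 + 0.5 * t))
        assert fit.m == pytest.approx(0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_trace_zero_slope(self):
        fit = fit_slope(_trace([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0]))
        assert fit.m == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        t = np.linspace(0, 4, 25)
        y = 1 + 0.3 * t + rng.normal(0, 0.05, t.size)
        y[0] = 1.0  # keep baseline positive and normalized
        fit = fit_slope(_trace(t, y))
        m, b, r2 = ols_oracle(t, y / y[0])
        assert fit.m == pytest.approx(m, abs=1e-9)
        assert fit.intercept == pytest.approx(b, abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, abs=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="insufficient|3"):
            fit_slope(_trace([0, 1], [1.0, 2.0]))


class TestSummarizeCondition:
    def test_mean_of_replicates(self):
        fits = [fit_slope(_trace([0, 1, 2], [1, 1 + m, 1 + 2 * m])) for m in (0.7, 0.8)]
        mean, sd = summarize_condition(fits)
        assert mean == pytest.approx(0.75, abs=1e-12)
        assert sd == pytest.approx(np.std([0.7, 0.8], ddof=1), abs=1e-12)

    def test_single_fit_warns_sd_zero(self):
        fit = fit_slope(_trace([0, 1, 2], [1.0, 1.5, 2.0]))
        with pytest.warns(UserWarning):
            mean, sd = summarize_condition([fit])
        assert mean == pytest.approx(fit.m)
        assert sd == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_condition([])

    def test_simulation_recovery_across_replicates(self):
        fits = []
        for seed in range(10):
            spec = small_movie_spec(
                true_slope_per_hour=0.4, noise_sigma=2.0, quantize=True, seed=seed
            )
            stack, _ = generate_movie(spec)
            fits.append(fit_slope(compute_trace(stack)))
        mean, _ = summarize_condition(fits)
        assert mean == pytest.approx(0.4, rel=0.05)


class TestEndpointRatios:
    def test_ratios(self):
        s = endpoint_ratios(3.0, 1.5, 40.0, 20.0)
        assert s.mfi_ratio == 2.0 and s.od_ratio == 2.0

    def test_identity(self):
        s = endpoint_ratios(2.0, 2.0, 7.0, 7.0)
        assert s.mfi_ratio == 1.0 and s.od_ratio == 1.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            endpoint_ratios(1.0, 0.0, 1.0, 1.0)


class TestLeakProfile:
    def _analyzed(self, spec):
        stack, truth = generate_movie(spec)
        trace = compute_trace(stack)
        return stack, trace.final_tissue, truth

    def test_uniform_medium_not_flagged(self):
        stack, tissue, _ = self._analyzed(small_movie_spec(noise_sigma=2, quantize=True))
        report = leak_profile(stack, tissue)
        assert not report.leak_flag and report.leak_bin is None

    @pytest.mark.parametrize("end,expected_bin", [(0, 0), (1, 9)])
    def test_port_blob_flagged_at_correct_end(self, end, expected_bin):
        spec = MovieSpec(noise_sigma=2, seed=11, port_leak=PortLeak(end=end))
        stack, tissue, truth = self._analyzed(spec)
        report = leak_profile(stack, tissue)
        assert report.leak_flag
        assert report.leak_bin == expected_bin
        assert truth.leak_end == end

    def test_infinite_threshold_never_flags(self):
        spec = MovieSpec(noise_sigma=2, seed=11, port_leak=PortLeak(end=1))
        stack, tissue, _ = self._analyzed(spec)
        report = leak_profile(stack, tissue, threshold_factor=np.inf)
        assert not report.leak_flag

    def test_degenerate_mask_falls_back_to_roi_axis(self, small_spec):
        stack, tissue, _ = self._analyzed(small_spec)
        round_mask = dataclasses.replace(tissue)
        rows, cols = np.indices(tissue.mask.shape)
        round_mask.mask = (rows - 60) ** 2 + (cols - 120) ** 2 <= 15**2
        with pytest.warns(UserWarning, match="near-circular"):
            report = leak_profile(stack, round_mask)
        assert report.n_bins == 10

    def test_too_few_bins_rejected(self, small_spec):
        stack, tissue, _ = self._analyzed(small_spec)
        with pytest.raises(ValueError):
            leak_profile(stack, tissue, n_bins=2)
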