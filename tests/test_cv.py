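"""Tests for ML delay estimation and CV conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehgcv import (
    AnalysisWindow,
    ChannelWeights,
    ContractionSegment,
    CVVector,
    DelayPair,
    ReferenceShape,
    SearchConfig,
    cost_e2,
    delays_to_cv,
    estimate_channel_weights,
    estimate_contraction_cv,
    estimate_delays,
    estimate_reference_shape,
    filter_outliers,
    plane_wave_delays,
    segment_contraction,
    synthesize_plane_wave_window,
    wrap_angle,
)

from _oracles import dft_shift_sse


class TestSegmentContraction:
    def test_40s_contraction_gives_7_windows(self, noiseless_recording):
        seg = ContractionSegment(onset_s=40.0, duration_s=40.0)
        wins = segment_contraction(seg, noiseless_recording, 10.0, 5.0)
        assert [w.start_s for w in wins] == [40.0 + 5.0 * k for k in range(7)]
        assert all(w.n_samples == 2000 for w in wins)

    def test_short_contraction_empty(self, noiseless_recording):
        seg = ContractionSegment(onset_s=40.0, duration_s=8.0)
        assert segment_contraction(seg, noiseless_recording, 10.0, 5.0) == []

    def test_exact_length_single_window(self, noiseless_recording):
        seg = ContractionSegment(onset_s=40.0, duration_s=10.0)
        wins = segment_contraction(seg, noiseless_recording, 10.0, 5.0)
        assert len(wins) == 1

    def test_window_not_longer_than_overlap_rejected(self, noiseless_recording):
        seg = ContractionSegment(onset_s=40.0, duration_s=40.0)
        with pytest.raises(ValueError):
            segment_contraction(seg, noiseless_recording, 5.0, 5.0)


def noise_window(variances, n=2000, fs=200.0, seed=0):
    rng = np.random.default_rng(seed)
    variances = np.asarray(variances, dtype=float)
    grid = rng.standard_normal((*variances.shape, n)) * np.sqrt(variances)[..., None]
    return AnalysisWindow(start_s=0.0, length_s=n / fs, grid_segment=grid, fs_hz=fs)


class TestChannelWeights:
    def test_equal_variance_noise_uniform_weights(self):
        w = estimate_channel_weights(noise_window(np.ones((2, 2)), n=1000)).weights
        assert np.all(np.abs(w - 1.0) < 0.2)

    def test_10x_noise_channel_weight_ratio(self):
        # oracle: weight ratio equals the direct noise-variance ratio 1/10
        var = np.ones((2, 2))
        var[0, 0] = 10.0
        w = estimate_channel_weights(noise_window(var, n=4000, seed=1)).weights
        others = np.delete(w.ravel(), 0)
        ratio = w[0, 0] / others.mean()
        assert abs(ratio - 0.1) < 0.03

    def test_dead_channel_weight_zero(self):
        var = np.ones((2, 2))
        win = noise_window(var, seed=2)
        win.grid_segment[1, 1] = 0.0
        w = estimate_channel_weights(win).weights
        assert w[1, 1] == 0.0
        assert np.all(w.ravel()[:-1] > 0)

    def test_all_dead_rejected(self):
        win = AnalysisWindow(0.0, 10.0, np.zeros((2, 2, 2000)), 200.0)
        with pytest.raises(ValueError):
            estimate_channel_weights(win)

    def test_residual_refinement_tracks_noise(self):
        window, truth = synthesize_plane_wave_window(8.0, 0.4, snr_db=10.0, rng=3)
        w = estimate_channel_weights(window, delays=truth).weights
        live = w[w > 0]
        assert abs(live.mean() - 1.0) < 1e-9  # mean-1 normalization
        assert np.all(np.abs(live - 1.0) < 0.5)  # equal-noise channels


class TestReferenceShape:
    def test_noiseless_realignment_recovers_source(self):
        window, truth = synthesize_plane_wave_window(10.0, np.pi / 4, rng=4)
        shape = estimate_reference_shape(window, truth)
        source = window.grid_segment[0, 0]  # zero-delay reference channel
        err = np.linalg.norm(shape.waveform() - source) / np.linalg.norm(source)
        assert err < 1e-6

    def test_single_channel_identity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400)
        win = AnalysisWindow(0.0, 2.0, x.reshape(1, 1, -1), 200.0)
        shape = estimate_reference_shape(win, DelayPair(0.0, 0.0))
        assert np.allclose(shape.spectrum, np.fft.rfft(x))

    def test_two_channel_equal_weight_mean(self):
        # oracle: direct two-term average of the realigned spectra
        rng = np.random.default_rng(6)
        grid = rng.standard_normal((1, 2, 400))
        fs, tau_c = 200.0, 0.0123
        win = AnalysisWindow(0.0, 2.0, grid, fs)
        shape = estimate_reference_shape(win, DelayPair(0.0, tau_c))
        f = np.fft.rfftfreq(400, d=1 / fs)
        x0 = np.fft.rfft(grid[0, 0])
        x1 = np.fft.rfft(grid[0, 1]) * np.exp(+2j * np.pi * f * tau_c)
        assert np.allclose(shape.spectrum, (x0 + x1) / 2.0)

    def test_nonfinite_delays_rejected(self):
        win = AnalysisWindow(0.0, 2.0, np.zeros((2, 2, 400)), 200.0)
        with pytest.raises(ValueError):
            estimate_reference_shape(win, DelayPair(np.nan, 0.0))


class TestCostE2:
    def test_noiseless_truth_near_zero(self):
        window, truth = synthesize_plane_wave_window(10.0, np.pi / 4, rng=7)
        shape = estimate_reference_shape(window, truth)
        energy = float(np.sum(window.grid_segment**2))
        assert cost_e2(truth, window, shape) < 1e-10 * energy

    def test_perturbed_delays_strictly_worse(self):
        window, truth = synthesize_plane_wave_window(10.0, np.pi / 4, rng=8)
        shape = estimate_reference_shape(window, truth)
        at_truth = cost_e2(truth, window, shape)
        perturbed = DelayPair(truth.tau_r_s * 1.5, truth.tau_c_s * 1.5)
        assert cost_e2(perturbed, window, shape) > at_truth

    def test_parseval_time_domain_oracle(self):
        # oracle: explicit per-channel fractional shift by direct inverse
        # DFT, then time-domain weighted SSE; odd length avoids the
        # real-Nyquist ambiguity of time-domain reconstruction
        rng = np.random.default_rng(9)
        n, fs = 401, 200.0
        grid = rng.standard_normal((2, 3, n))
        win = AnalysisWindow(0.0, n / fs, grid, fs)
        spec = np.fft.rfft(rng.standard_normal(n))
        shape = ReferenceShape(spectrum=spec, n_samples=n)
        w = rng.uniform(0.5, 2.0, size=(2, 3))
        delays = DelayPair(0.013, -0.004)
        got = cost_e2(delays, win, shape, ChannelWeights(w))
        expected = dft_shift_sse(grid, spec, fs, 0.013, -0.004, w)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_common_time_shift_invariance(self):
        rng = np.random.default_rng(10)
        n, fs, k = 400, 200.0, 17
        grid = rng.standard_normal((2, 2, n))
        spec = np.fft.rfft(rng.standard_normal(n))
        delays = DelayPair(0.007, 0.011)
        win = AnalysisWindow(0.0, n / fs, grid, fs)
        c1 = cost_e2(delays, win, ReferenceShape(spec, n))
        rolled = AnalysisWindow(0.0, n / fs, np.roll(grid, k, axis=2), fs)
        f = np.fft.rfftfreq(n, d=1 / fs)
        spec_shifted = spec * np.exp(-2j * np.pi * f * k / fs)
        c2 = cost_e2(delays, rolled, ReferenceShape(spec_shifted, n))
        assert c2 == pytest.approx(c1, rel=1e-9)

    def test_length_mismatch_rejected(self):
        win = AnalysisWindow(0.0, 2.0, np.zeros((2, 2, 400)), 200.0)
        shape = ReferenceShape(np.zeros(101, dtype=complex), 200)
        with pytest.raises(ValueError):
            cost_e2(DelayPair(0.0, 0.0), win, shape)


class TestEstimateDelays:
    def test_noiseless_cv10_theta_quarter_pi(self):
        window, truth = synthesize_plane_wave_window(10.0, np.pi / 4, rng=11)
        est = estimate_delays(window)
        assert truth.tau_r_s == pytest.approx(0.5 * math.cos(math.pi / 4) / 10.0)
        assert abs(est.tau_r_s - truth.tau_r_s) < 1e-4
        assert abs(est.tau_c_s - truth.tau_c_s) < 1e-4
        assert est.converged

    def test_monte_carlo_mean_tau_r(self):
        # oracle: the generator's ground truth d/CV = 0.0625 s
        taus = []
        for rep in range(100):
            window, _ = synthesize_plane_wave_window(
                8.0, 0.0, snr_db=10.0, rng=1000 + rep
            )
            weights = estimate_channel_weights(window)
            taus.append(estimate_delays(window, weights).tau_r_s)
        assert abs(np.mean(taus) - 0.5 / 8.0) < 0.05 * (0.5 / 8.0)

    def test_short_window_rejected(self):
        win = AnalysisWindow(0.0, 0.5, np.zeros((2, 2, 100)), 200.0)
        with pytest.raises(ValueError):
            estimate_delays(win)

    def test_single_live_row_rejected(self):
        window, _ = synthesize_plane_wave_window(
            10.0, 0.0, n_rows=3, n_cols=3, rng=12
        )
        w = np.ones((3, 3))
        w[1:, :] = 0.0  # kill all but the first row
        with pytest.raises(ValueError):
            estimate_delays(window, ChannelWeights(w * 9 / 3))

    def test_warm_start_skips_coarse_search(self):
        window, truth = synthesize_plane_wave_window(10.0, 0.5, rng=13)
        est = estimate_delays(window, init=truth)
        assert abs(est.tau_r_s - truth.tau_r_s) < 1e-4
        assert abs(est.tau_c_s - truth.tau_c_s) < 1e-4


class TestDelaysToCv:
    def test_vertical_propagation(self):
        v = delays_to_cv(DelayPair(0.05, 0.0), 0.5)
        assert v.amplitude_cm_s == pytest.approx(10.0)
        assert v.angle_rad == pytest.approx(0.0)

    def test_leftward_propagation(self):
        v = delays_to_cv(DelayPair(0.0, -0.05), 0.5)
        assert v.amplitude_cm_s == pytest.approx(10.0)
        assert v.angle_rad == pytest.approx(-math.pi / 2)

    def test_zero_delay_excluded(self):
        v = delays_to_cv(DelayPair(0.0, 0.0), 0.5)
        assert v.excluded and v.reason == "zero-delay"

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            delays_to_cv(DelayPair(0.05, 0.0), 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        cv=st.floats(0.5, 30.0),
        theta=st.floats(-math.pi, math.pi),
        d=st.floats(0.1, 2.0),
    )
    def test_round_trip_property(self, cv, theta, d):
        tau_r, tau_c = plane_wave_delays(cv, theta, d)
        v = delays_to_cv(DelayPair(tau_r, tau_c), d)
        assert v.amplitude_cm_s == pytest.approx(cv, rel=1e-12)
        assert abs(wrap_angle(v.angle_rad - theta)) < 1e-9


class TestFilterOutliers:
    def test_middle_outlier_excluded(self):
        cvs = [CVVector(a, 0.0) for a in (8.0, 35.0, 12.0)]
        out = filter_outliers(cvs)
        assert [v.excluded for v in out] == [False, True, False]
        assert out[1].reason == "supra-physiological"
        assert [v.amplitude_cm_s for v in out] == [8.0, 35.0, 12.0]

    def test_exactly_30_retained(self):
        out = filter_outliers([CVVector(30.0, 0.0)])
        assert not out[0].excluded

    def test_empty_list(self):
        assert filter_outliers([]) == []


class TestEstimateContractionCv:
    def test_noiseless_recording_end_to_end(self, noiseless_recording):
        seg = ContractionSegment(onset_s=40.0, duration_s=40.0)
        results = estimate_contraction_cv(
            noiseless_recording, seg, search_cfg=SearchConfig(cv_min_cm_s=2.0)
        )
        assert len(results) == 7
        kept = [v for _, _, v in results if not v.excluded]
        assert len(kept) >= 6
        for v in kept:
            assert v.amplitude_cm_s == pytest.approx(10.0, rel=0.02)
            assert abs(wrap_angle(v.angle_rad)) < 0.05
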