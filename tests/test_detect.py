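"""Tests for eIUP estimation and contraction detection/confirmation."""

import numpy as np
import pytest

from ehgcv import (
    ContractionSegment,
    IUPEstimate,
    compute_spectrogram,
    confirm_contractions,
    detect_contractions,
    estimate_iup,
)


def sinusoid(f_hz, fs_hz, duration_s, amp=1.0):
    t = np.arange(int(duration_s * fs_hz)) / fs_hz
    return amp * np.sin(2 * np.pi * f_hz * t)


class TestSpectrogram:
    def test_sinusoid_peak_in_every_frame(self):
        fs = 20.0
        spec = compute_spectrogram(sinusoid(0.5, fs, 200.0), fs, window_s=20.0)
        peak_freqs = spec.freqs_hz[np.argmax(spec.power, axis=1)]
        assert np.all(np.abs(peak_freqs - 0.5) < 0.05)

    def test_zero_signal_zero_power(self):
        spec = compute_spectrogram(np.zeros(4000), 20.0)
        assert np.all(spec.power == 0.0)

    def test_parseval_white_noise(self):
        # oracle: direct time-domain variance; mean per-frame band integral
        # of the density-scaled PSD must match within 5%
        rng = np.random.default_rng(0)
        fs = 20.0
        x = rng.standard_normal(int(600 * fs))
        spec = compute_spectrogram(x, fs)
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        frame_power = spec.power.sum(axis=1) * df
        assert abs(frame_power.mean() / x.var() - 1.0) < 0.05

    def test_frequency_resolution_in_band(self):
        spec = compute_spectrogram(np.ones(4000), 20.0)
        assert np.all(np.diff(spec.freqs_hz) <= 0.1 + 1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(np.zeros(100), 20.0, window_s=20.0)

    def test_bad_hop_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(np.zeros(4000), 20.0, window_s=20.0, hop_s=25.0)


class TestEstimateIup:
    def test_single_inband_line(self):
        fs = 20.0
        spec = compute_spectrogram(sinusoid(0.5, fs, 200.0), fs)
        iup = estimate_iup(spec)
        interior = iup.psi[2:-2]
        # constant-amplitude line: psi approximately constant over frames
        assert np.ptp(interior) < 0.02 * interior.mean()
        # single line at 0.5 Hz: psi ~= 0.5 * (in-band power)
        band = (spec.freqs_hz >= 0.3) & (spec.freqs_hz <= 0.8)
        in_band_power = spec.power[2:-2, band].sum(axis=1)
        assert np.allclose(interior, 0.5 * in_band_power, rtol=0.02)

    def test_out_of_band_line_near_zero(self):
        fs = 20.0
        spec_out = compute_spectrogram(sinusoid(2.0, fs, 200.0), fs)
        spec_in = compute_spectrogram(sinusoid(0.5, fs, 200.0), fs)
        psi_out = estimate_iup(spec_out).psi
        psi_in = estimate_iup(spec_in).psi
        assert psi_out.max() < 1e-6 * psi_in.max()

    def test_two_line_signal_matches_bin_sum_oracle(self):
        fs = 20.0
        x = sinusoid(0.4, fs, 200.0) + sinusoid(0.6, fs, 200.0)
        spec = compute_spectrogram(x, fs)
        iup = estimate_iup(spec)
        # oracle: direct summation over DFT bins, explicit loop
        for i in range(spec.power.shape[0]):
            expected = sum(
                f * p
                for f, p in zip(spec.freqs_hz, spec.power[i])
                if 0.3 <= f <= 0.8
            )
            assert iup.psi[i] == pytest.approx(expected, rel=1e-12)
        # equal-power lines P at 0.4 and 0.6 Hz: psi ~= 0.4P + 0.6P = P
        band = (spec.freqs_hz >= 0.3) & (spec.freqs_hz <= 0.8)
        p_line = spec.power[2:-2, band].sum(axis=1) / 2.0
        assert np.allclose(iup.psi[2:-2], 1.0 * p_line, rtol=0.05)

    def test_psi_additivity_disjoint_lines(self):
        fs = 20.0
        a = sinusoid(0.4, fs, 200.0)
        b = sinusoid(0.7, fs, 200.0)
        psi_a = estimate_iup(compute_spectrogram(a, fs)).psi
        psi_b = estimate_iup(compute_spectrogram(b, fs)).psi
        psi_ab = estimate_iup(compute_spectrogram(a + b, fs)).psi
        assert np.allclose(psi_ab, psi_a + psi_b, rtol=0.02, atol=1e-9 * psi_ab.max())

    def test_band_outside_range_rejected(self):
        spec = compute_spectrogram(np.zeros(4000), 20.0)
        with pytest.raises(ValueError):
            estimate_iup(spec, f_min_hz=0.3, f_max_hz=spec.freqs_hz[-1] + 1.0)


def make_iup(psi):
    times = np.arange(len(psi), dtype=float)
    return IUPEstimate(psi=np.asarray(psi, dtype=float), frame_times_s=times)


class TestDetectContractions:
    def test_flat_psi_zero_segments(self):
        assert detect_contractions(make_iup(np.ones(400))) == []

    def test_three_rectangular_bumps(self):
        # ground truth from the constructed schedule: 40 s bumps at 10x
        # baseline starting at 50, 170, 290 s (frame hop 1 s)
        psi = np.ones(400)
        for onset in (50, 170, 290):
            psi[onset : onset + 40] = 10.0
        segments = detect_contractions(make_iup(psi))
        assert len(segments) == 3
        for seg, onset in zip(segments, (50.0, 170.0, 290.0)):
            assert abs(seg.onset_s - onset) <= 1.0  # within one frame hop
            assert abs(seg.duration_s - 40.0) <= 2.0

    def test_close_bumps_merged(self):
        # two bumps separated by less than one frame hop form one segment
        psi = np.ones(400)
        psi[100:130] = 10.0
        psi[130:160] = 8.0
        segments = detect_contractions(make_iup(psi))
        assert len(segments) == 1
        assert segments[0].onset_s <= 100.0
        assert segments[0].end_s >= 159.0

    def test_short_runs_dropped(self):
        psi = np.ones(400)
        psi[200:205] = 10.0  # 5 s burst < min_duration_s=20
        assert detect_contractions(make_iup(psi)) == []

    def test_segments_disjoint_and_sorted(self):
        rng = np.random.default_rng(2)
        psi = 1.0 + 0.1 * rng.random(400)
        for onset in (60, 150, 260, 320):
            psi[onset : onset + 35] += 9.0
        segments = detect_contractions(make_iup(psi))
        for a, b in zip(segments, segments[1:]):
            assert a.end_s <= b.onset_s

    def test_empty_iup_rejected(self):
        with pytest.raises(ValueError):
            detect_contractions(make_iup([]))

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            detect_contractions(make_iup(np.ones(60)))


class TestConfirmContractions:
    def test_toco_overlap_kept(self):
        seg = ContractionSegment(onset_s=100.0, duration_s=60.0)
        out = confirm_contractions([seg], [(120.0, 30.0)], [])
        assert len(out) == 1
        assert out[0].confirmed_by == frozenset({"toco"})

    def test_far_perception_dropped(self):
        seg = ContractionSegment(onset_s=100.0, duration_s=60.0)
        assert confirm_contractions([seg], [], [400.0]) == []

    def test_perception_within_slack_kept(self):
        seg = ContractionSegment(onset_s=100.0, duration_s=60.0)
        out = confirm_contractions([seg], [], [165.0], perception_slack_s=30.0)
        assert len(out) == 1
        assert out[0].confirmed_by == frozenset({"perception"})

    def test_both_criteria_recorded(self):
        seg = ContractionSegment(onset_s=100.0, duration_s=60.0)
        out = confirm_contractions([seg], [(90.0, 20.0)], [130.0])
        assert out[0].confirmed_by == frozenset({"toco", "perception"})

    def test_touching_toco_interval_not_overlap(self):
        # zero-length intersection does not count as overlap
        seg = ContractionSegment(onset_s=100.0, duration_s=60.0)
        assert confirm_contractions([seg], [(160.0, 20.0)], []) == []


class TestEndToEndDetection:
    def test_simulated_recording(self, three_contraction_recording):
        rec = three_contraction_recording
        spec = compute_spectrogram(rec.bipolar_signal, rec.fs_hz)
        iup = estimate_iup(spec)
        segments = detect_contractions(iup)
        confirmed = confirm_contractions(
            segments, rec.toco_marks, rec.perception_marks
        )
        assert len(confirmed) == 3
        for seg, (onset, _) in zip(confirmed, rec.toco_marks):
            assert abs(seg.onset_s - onset) < 10.0
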