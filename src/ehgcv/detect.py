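"""Contraction detection from the bipolar EHG channel.

The estimated intrauterine pressure (eIUP) surrogate is the unnormalized
first statistical moment of the bipolar spectrogram over the 0.3-0.8 Hz
band,

    Psi(n) = sum_{f in [f_min, f_max]} f * rho(n, f),

which rises and falls with each uterine contraction.  Contractions are
detected by an adaptive threshold computed in overlapping 60 s windows
(per-window median + k * MAD with an absolute floor), then confirmed
against tocodynamometer intervals and maternal-perception instants.  Psi
is used for timing only; no intrauterine-pressure amplitude calibration is
attempted.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import ContractionSegment, IUPEstimate, Spectrogram

__all__ = [
    "compute_spectrogram",
    "estimate_iup",
    "detect_contractions",
    "confirm_contractions",
]

#: Default STFT parameters: Hann window of 20 s, 5 s hop, zero-padded to
#: 0.025 Hz bin spacing (>= 20 bins across the 0.3-0.8 Hz band).
DEFAULT_WINDOW_S = 20.0
DEFAULT_HOP_S = 5.0
DEFAULT_BIN_SPACING_HZ = 0.025


def compute_spectrogram(
    signal: np.ndarray,
    fs_hz: float,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    bin_spacing_hz: float = DEFAULT_BIN_SPACING_HZ,
) -> Spectrogram:
    """Short-time power spectral density rho(n, f) of a 1-D signal.

    Hann-windowed, density-scaled (so the band integral of a frame
    approximates the signal variance within that frame), zero-padded to
    ``bin_spacing_hz`` for fine bin spacing across the contraction band.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * fs_hz))
    if nperseg < 16:
        raise ValueError("window must span at least 16 samples")
    hop = int(round(hop_s * fs_hz))
    if hop > nperseg or hop < 1:
        raise ValueError("hop_s must be positive and at most window_s")
    if signal.size < nperseg:
        raise ValueError("signal shorter than one analysis window")
    nfft = max(nperseg, int(np.ceil(fs_hz / bin_spacing_hz)))
    freqs, times, power = sps.spectrogram(
        signal,
        fs=fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        nfft=nfft,
        scaling="density",
        mode="psd",
        detrend=False,
    )
    return Spectrogram(
        power=power.T,  # (frame, freq)
        frame_times_s=times,
        freqs_hz=freqs,
        frame_hop_s=hop / fs_hz,
    )


def estimate_iup(
    spec: Spectrogram, f_min_hz: float = 0.3, f_max_hz: float = 0.8
) -> IUPEstimate:
    """Unnormalized first spectral moment per frame over [f_min, f_max].

    Band bounds are inclusive; only in-band bins contribute.
    """
    if f_min_hz < spec.freqs_hz[0] or f_max_hz > spec.freqs_hz[-1]:
        raise ValueError("requested band lies outside the spectrogram range")
    band = (spec.freqs_hz >= f_min_hz) & (spec.freqs_hz <= f_max_hz)
    psi = spec.power[:, band] @ spec.freqs_hz[band]
    return IUPEstimate(
        psi=psi,
        frame_times_s=spec.frame_times_s.copy(),
        f_min_hz=f_min_hz,
        f_max_hz=f_max_hz,
    )


def _active_frames(
    psi: np.ndarray,
    times: np.ndarray,
    window_s: float,
    k_sigma: float,
    floor_frac: float,
) -> np.ndarray:
    """Union of per-window supra-threshold masks.

    Each 60 s window (50% overlap) thresholds at its median + k * robust
    spread (1.4826*MAD), floored at ``floor_frac`` of the global psi range
    so that flat stretches do not produce a zero threshold.
    """
    span = times[-1] - times[0]
    floor = floor_frac * max(np.ptp(psi), np.finfo(float).tiny)
    active = np.zeros(psi.size, dtype=bool)
    hop = window_s / 2.0
    n_windows = max(1, int(np.floor((span - window_s) / hop)) + 1)
    for i in range(n_windows):
        t0 = times[0] + i * hop
        t1 = t0 + window_s
        if i == n_windows - 1:
            t1 = times[-1] + 1e-9  # last window absorbs the remainder
        m = (times >= t0) & (times <= t1)
        if not np.any(m):
            continue
        local = psi[m]
        spread = 1.4826 * np.median(np.abs(local - np.median(local)))
        thresh = np.median(local) + k_sigma * max(spread, floor)
        active[m] |= local > thresh
    return active


def detect_contractions(
    iup: IUPEstimate,
    window_s: float = 60.0,
    min_duration_s: float = 20.0,
    k_sigma: float = 3.0,
    floor_frac: float = 0.05,
) -> list[ContractionSegment]:
    """Detect contraction onset/duration from the eIUP with an adaptive
    threshold in overlapping 60 s windows.

    Supra-threshold runs are merged across windows (gaps shorter than one
    frame hop are bridged), each run's extent is widened outward to a low
    edge boundary (baseline + 5% of the run's peak excursion, floored at
    the global robust spread) so onset/offset track the burst edges
    rather than the much higher adaptive threshold, and runs shorter than
    ``min_duration_s`` are dropped.  Returned segments are disjoint and
    time-ordered.
    """
    psi = iup.psi
    times = iup.frame_times_s
    if psi.size == 0:
        raise ValueError("empty eIUP")
    if times[-1] - times[0] < 2 * window_s:
        raise ValueError("eIUP must span at least two adaptive-threshold windows")

    active = _active_frames(psi, times, window_s, k_sigma, floor_frac)
    hop = float(np.median(np.diff(times))) if times.size > 1 else 1.0

    # contiguous runs of active frames
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(active)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        runs = list(zip(starts, ends))

    # merge runs separated by less than one frame hop
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and times[s] - times[merged[-1][1]] <= hop + 1e-9:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # refine run extents: the adaptive threshold sits well above the burst
    # edges, so each run is extended outward to a low boundary -- baseline
    # plus 5% of the run's peak excursion (floored at the global noise
    # spread) -- which tracks the true onset/offset of the burst.
    baseline = float(np.median(psi))
    spread = 1.4826 * float(np.median(np.abs(psi - baseline)))
    refined: list[tuple[int, int, float]] = []
    for s, e in merged:
        peak = float(psi[s : e + 1].max())
        edge = baseline + max(0.05 * (peak - baseline), k_sigma * spread)
        s2 = s
        while s2 > 0 and psi[s2 - 1] >= edge:
            s2 -= 1
        e2 = e
        while e2 < psi.size - 1 and psi[e2 + 1] >= edge:
            e2 += 1
        if refined and s2 <= refined[-1][1]:  # extension overlapped previous run
            ps, pe, ppk = refined[-1]
            refined[-1] = (ps, max(e2, pe), max(peak, ppk))
        else:
            refined.append((s2, e2, peak))

    segments: list[ContractionSegment] = []
    for s2, e2, peak in refined:
        # the edge crossing happened between the last sub- and the first
        # supra-edge frame; take the midpoint of that interval
        onset = float(times[s2]) - hop / 2.0
        offset = float(times[e2]) + hop / 2.0
        if offset - onset < min_duration_s:
            continue
        segments.append(
            ContractionSegment(
                onset_s=max(onset, 0.0),
                duration_s=offset - onset,
                peak_psi=peak,
            )
        )

    # enforce disjoint, sorted output
    segments.sort(key=lambda seg: seg.onset_s)
    for a, b in zip(segments, segments[1:]):
        assert a.end_s <= b.onset_s + 1e-9, "detected segments must be disjoint"
    return segments


def confirm_contractions(
    segments: list[ContractionSegment],
    toco_marks: list[tuple[float, float]],
    perception_marks: list[float],
    perception_slack_s: float = 30.0,
) -> list[ContractionSegment]:
    """Keep only segments corroborated by external evidence.

    A segment survives iff it overlaps (any nonzero intersection) a
    tocodynamometer interval, or a maternal-perception instant falls
    within the segment extended by ``perception_slack_s`` on both sides.
    ``confirmed_by`` records which criteria fired.
    """
    out: list[ContractionSegment] = []
    for seg in segments:
        by: set[str] = set()
        for onset, dur in toco_marks:
            if min(seg.end_s, onset + dur) - max(seg.onset_s, onset) > 0:
                by.add("toco")
                break
        for t in perception_marks:
            if seg.onset_s - perception_slack_s <= t <= seg.end_s + perception_slack_s:
                by.add("perception")
                break
        if by:
            out.append(
                ContractionSegment(
                    onset_s=seg.onset_s,
                    duration_s=seg.duration_s,
                    peak_psi=seg.peak_psi,
                    confirmed_by=frozenset(by),
                    source_recording=seg.source_recording,
                )
            )
    return out
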