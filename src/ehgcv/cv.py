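"""Maximum-likelihood 2-D conduction-velocity estimation on an electrode grid.

Under the plane-wave model every grid channel records the same reference
shape s(n), delayed linearly in row and column index, plus white Gaussian
noise.  Maximum-likelihood estimation of the inter-row/inter-column delay
pair (tau_r, tau_c) is then equivalent to minimizing the weighted spectral
cost

    E^2(tau_r, tau_c) = sum_rc w_rc sum_f |X_rc(f) - S(f) e^{-j2pi f [(r-1)tau_r + (c-1)tau_c]}|^2,

where X_rc(f) and S(f) are the Fourier transforms of channel (r, c) and of
the reference shape, and the channel weights w_rc are inversely
proportional to the estimated channel noise.  Working in the frequency
domain makes the delays continuous parameters, free of the sampling-grid
resolution limit.  The delay pair maps to the CV vector through

    tau_r = d cos(theta) / CV,   tau_c = d sin(theta) / CV,

for interelectrode distance d, inverted as CV = d / sqrt(tau_r^2 + tau_c^2)
and theta = atan2(tau_c, tau_r).  Estimated CV amplitudes above 30 cm/s are
supra-physiological and marked as outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .types import (
    AnalysisWindow,
    ChannelWeights,
    ContractionSegment,
    CVVector,
    DelayPair,
    GridRecording,
    ReferenceShape,
)

__all__ = [
    "SearchConfig",
    "segment_contraction",
    "estimate_channel_weights",
    "estimate_reference_shape",
    "cost_e2",
    "estimate_delays",
    "delays_to_cv",
    "filter_outliers",
    "bandpass_grid",
    "estimate_contraction_cv",
]

#: CV values above this are considered non-propagating artifacts (cm/s).
MAX_PHYSIOLOGICAL_CV_CM_S = 30.0


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the delay search.

    ``cv_min_cm_s`` sets the half-range of the coarse grid search,
    tau_max = d / cv_min: anything propagating slower than ``cv_min`` is
    treated as non-propagating.  ``coarse_step_s`` defaults to half a
    sample period.  The alternating refinement (re-estimate shape, then
    locally minimize the cost) stops when the delay update falls below
    ``tol_s`` or after ``max_iter`` outer iterations.
    """

    electrode_spacing_cm: float = 0.5
    cv_min_cm_s: float = 1.0
    coarse_step_s: float | None = None
    max_iter: int = 20
    tol_s: float = 1e-5

    @property
    def tau_max_s(self) -> float:
        return self.electrode_spacing_cm / self.cv_min_cm_s


def segment_contraction(
    contraction: ContractionSegment,
    recording: GridRecording,
    window_length_s: float = 10.0,
    overlap_s: float = 5.0,
) -> list[AnalysisWindow]:
    """Cut a contraction into overlapping analysis windows.

    Consecutive windows advance by ``window_length_s - overlap_s``; a
    trailing partial window is dropped.  A contraction shorter than one
    window yields an empty list.
    """
    if window_length_s <= overlap_s:
        raise ValueError("window_length_s must exceed overlap_s")
    fs = recording.fs_hz
    step = window_length_s - overlap_s
    n_win = int(round(window_length_s * fs))
    start = max(contraction.onset_s, 0.0)
    end = min(contraction.end_s, recording.duration_s)
    out: list[AnalysisWindow] = []
    t = start
    k = 0
    while t + window_length_s <= end + 1e-9:
        i0 = int(round(t * fs))
        seg = recording.grid_signals[:, :, i0 : i0 + n_win]
        if seg.shape[2] < n_win:
            break
        out.append(
            AnalysisWindow(
                start_s=t,
                length_s=window_length_s,
                grid_segment=seg.copy(),
                fs_hz=fs,
                parent_contraction=f"{contraction.onset_s:.1f}s",
            )
        )
        k += 1
        t = start + k * step
    return out


def bandpass_grid(
    grid: np.ndarray, fs_hz: float, f_band_hz: tuple[float, float] = (0.3, 5.0)
) -> np.ndarray:
    """Zero-phase band-pass of every grid channel.

    Removes drift/DC below the band and out-of-band noise above it before
    delay estimation; zero-phase filtering leaves inter-channel delays
    untouched.
    """
    sos = sps.butter(4, f_band_hz, btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, grid, axis=-1)


# ---------------------------------------------------------------------------
# spectral machinery


def _phase_factors(
    n_rows: int, n_cols: int, freqs_hz: np.ndarray, tau_r_s: float, tau_c_s: float
) -> np.ndarray:
    """exp(-j 2 pi f [(r-1) tau_r + (c-1) tau_c]) as an (R, C, F) array."""
    r = np.arange(n_rows)[:, None, None]
    c = np.arange(n_cols)[None, :, None]
    return np.exp(-2j * np.pi * freqs_hz[None, None, :] * (r * tau_r_s + c * tau_c_s))


def _parseval_bin_weights(n: int) -> np.ndarray:
    """One-sided bin weights making (1/N) sum_k pw_k |X_k|^2 == sum_n x_n^2."""
    m = n // 2 + 1
    pw = np.full(m, 2.0)
    pw[0] = 1.0
    if n % 2 == 0:
        pw[-1] = 1.0
    return pw


def _reference_spectrum(
    X: np.ndarray, freqs: np.ndarray, tau_r: float, tau_c: float, w: np.ndarray
) -> np.ndarray:
    """Weighted average of channel spectra re-aligned to a common origin:
    the least-squares-optimal S(f) given the delays."""
    phase = _phase_factors(X.shape[0], X.shape[1], freqs, tau_r, tau_c)
    return np.tensordot(w, X * np.conj(phase), axes=([0, 1], [0, 1])) / w.sum()


def _cost_from_spectra(
    X: np.ndarray,
    S: np.ndarray,
    freqs: np.ndarray,
    tau_r: float,
    tau_c: float,
    w: np.ndarray,
    pw: np.ndarray,
    n: int,
) -> float:
    phase = _phase_factors(X.shape[0], X.shape[1], freqs, tau_r, tau_c)
    resid = X - S[None, None, :] * phase
    per_channel = np.tensordot(np.abs(resid) ** 2, pw, axes=([2], [0])) / n
    return float(np.sum(w * per_channel))


def estimate_reference_shape(
    window: AnalysisWindow,
    delays: DelayPair,
    weights: ChannelWeights | None = None,
) -> ReferenceShape:
    """Estimate the common shape spectrum S(f) given a delay pair.

    Channels are re-aligned to the (1, 1) origin by undoing their modeled
    phase delays, then averaged with the channel weights -- the
    least-squares-optimal S(f) for the given (tau_r, tau_c).
    """
    if not (np.isfinite(delays.tau_r_s) and np.isfinite(delays.tau_c_s)):
        raise ValueError("delays must be finite")
    seg = window.grid_segment
    n = seg.shape[2]
    X = rfft(seg, axis=2)
    freqs = rfftfreq(n, d=1.0 / window.fs_hz)
    w = _resolve_weights(weights, seg.shape[0], seg.shape[1])
    S = _reference_spectrum(X, freqs, delays.tau_r_s, delays.tau_c_s, w)
    return ReferenceShape(spectrum=S, n_samples=n)


def cost_e2(
    delays: DelayPair,
    window: AnalysisWindow,
    shape: ReferenceShape,
    weights: ChannelWeights | None = None,
) -> float:
    """Weighted sum of squared spectral residuals E^2 at a delay pair.

    By Parseval the value equals the time-domain weighted sum of squared
    differences between each channel and the fractionally-shifted
    reference shape.  Zero (to numerical precision) when the window obeys
    the noiseless plane-wave model at the given delays.
    """
    seg = window.grid_segment
    n = seg.shape[2]
    if shape.n_samples != n:
        raise ValueError("reference shape and window lengths differ")
    X = rfft(seg, axis=2)
    freqs = rfftfreq(n, d=1.0 / window.fs_hz)
    w = _resolve_weights(weights, seg.shape[0], seg.shape[1])
    pw = _parseval_bin_weights(n)
    return _cost_from_spectra(
        X, shape.spectrum, freqs, delays.tau_r_s, delays.tau_c_s, w, pw, n
    )


def _resolve_weights(
    weights: ChannelWeights | None, n_rows: int, n_cols: int
) -> np.ndarray:
    if weights is None:
        return np.ones((n_rows, n_cols))
    w = weights.weights
    if w.shape != (n_rows, n_cols):
        raise ValueError("weights shape does not match the grid")
    return w


def estimate_channel_weights(
    window: AnalysisWindow,
    delays: DelayPair | None = None,
    shape: ReferenceShape | None = None,
    hf_cutoff_hz: float = 10.0,
) -> ChannelWeights:
    """Per-channel weights inversely proportional to estimated noise.

    Without a delay estimate the channel noise variance is read from the
    high-frequency (> ``hf_cutoff_hz``) power, where the white noise floor
    dominates the band-limited physiological content.  Given a delay pair
    (and optionally a pre-computed reference shape), the noise is
    re-estimated as the variance of the residual after subtracting the
    re-aligned reference shape.  Weights are normalized to mean 1 over
    live channels; dead channels (zero total variance) get weight 0; if
    every live channel reports (numerically) zero noise, the weights fall
    back to uniform.
    """
    seg = window.grid_segment
    n_rows, n_cols, n = seg.shape
    if n_rows * n_cols < 2:
        raise ValueError("need at least 2 channels to weight")
    total_var = seg.var(axis=2)
    dead = total_var <= 1e-12 * max(total_var.max(), np.finfo(float).tiny)
    if dead.all():
        raise ValueError("all channels are dead")

    if delays is None:
        nyq = window.fs_hz / 2.0
        if hf_cutoff_hz >= nyq:
            raise ValueError("hf_cutoff_hz must be below Nyquist")
        sos = sps.butter(4, hf_cutoff_hz, btype="highpass", fs=window.fs_hz, output="sos")
        hf = sps.sosfiltfilt(sos, seg, axis=2)
        # white-noise variance from its share of the band above the cutoff
        band_frac = (nyq - hf_cutoff_hz) / nyq
        noise_var = hf.var(axis=2) / band_frac
    else:
        if shape is None:
            shape = estimate_reference_shape(window, delays)
        X = rfft(seg, axis=2)
        freqs = rfftfreq(n, d=1.0 / window.fs_hz)
        phase = _phase_factors(n_rows, n_cols, freqs, delays.tau_r_s, delays.tau_c_s)
        resid = irfft(X - shape.spectrum[None, None, :] * phase, n=n, axis=2)
        noise_var = resid.var(axis=2)

    floor = 1e-6 * max(float(total_var.max()), np.finfo(float).tiny)
    w = 1.0 / np.maximum(noise_var, floor)
    w[dead] = 0.0
    live = ~dead
    w[live] /= w[live].mean()
    return ChannelWeights(weights=w)


# ---------------------------------------------------------------------------
# delay search


def _coarse_search(
    seg: np.ndarray,
    fs: float,
    w: np.ndarray,
    tau_max_s: float,
    step_s: float,
) -> tuple[float, float]:
    """Exhaustive search of the concentrated ML objective on a delay grid.

    With S(f) replaced by its optimal value for each candidate pair,
    minimizing E^2 is equivalent to maximizing the energy of the weighted
    re-aligned channel sum.  That objective expands into pairwise channel
    cross-correlations grouped by (row offset, column offset), which are
    evaluated on the candidate grid by band-limited interpolation of the
    cross-correlation functions.
    """
    n_rows, n_cols, n = seg.shape
    dt = 1.0 / fs
    up = max(1, int(round(dt / step_s)))
    step = dt / up
    n_t = int(np.floor(tau_max_s / step))
    span_lags = (max(n_rows, n_cols) - 1) * n_t  # largest class lag in steps

    nfft = next_fast_len(2 * n)
    # guard: the interpolated correlation must cover the largest class lag
    while (nfft * up) // 2 <= span_lags + up:
        nfft = next_fast_len(nfft + n)
    Y = rfft(seg, n=nfft, axis=2) * w[:, :, None]
    m_up = nfft * up

    a = np.arange(-n_t, n_t + 1)
    q = np.zeros((a.size, a.size))
    for dr in range(n_rows):
        for dc in range(-(n_cols - 1), n_cols):
            if dr == 0 and dc <= 0:
                continue  # (0,0) is constant; negative classes by symmetry
            r0 = dr
            c0, c1 = max(dc, 0), n_cols + min(dc, 0)
            P = np.einsum(
                "rcf,rcf->f",
                Y[r0:, c0:c1],
                np.conj(Y[: n_rows - dr, c0 - dc : c1 - dc]),
            )
            corr = irfft(P, n=m_up) * up  # lag step = dt/up, wraps negatives
            lag_idx = (dr * a[:, None] + dc * a[None, :]) % m_up
            q += 2.0 * corr[lag_idx]
    i, j = np.unravel_index(np.argmax(q), q.shape)
    return float(a[i] * step), float(a[j] * step)


def _concentrated_cost(
    X: np.ndarray,
    freqs: np.ndarray,
    tau_r: float,
    tau_c: float,
    w: np.ndarray,
    pw: np.ndarray,
    n: int,
    const: float,
) -> float:
    """E^2 with the reference shape profiled out.

    For any candidate delay pair the least-squares-optimal S(f) is the
    weighted mean of the re-aligned channel spectra, so

        E^2(tau) = sum_rc w |X_rc|^2 - (sum w) |S_opt|^2

    per frequency bin; ``const`` carries the first (delay-independent)
    term.  Evaluating this is one shape re-estimation plus one cost
    evaluation, fused.
    """
    phase = _phase_factors(X.shape[0], X.shape[1], freqs, tau_r, tau_c)
    S = np.tensordot(w, X * np.conj(phase), axes=([0, 1], [0, 1])) / w.sum()
    fit = float(w.sum() * np.dot(pw, np.abs(S) ** 2) / n)
    return const - fit


def _newton_polish(fun, x: np.ndarray, h: float = 1e-6, max_steps: int = 4):
    """A few Newton steps on a smooth 2-D cost via central differences.

    The simplex search stops within its tolerance of the minimum; the
    cost is locally quadratic there, so Newton polishing converges to the
    optimum at machine precision in 2-3 steps.  Falls back to the input
    point whenever a step fails to decrease the cost.
    """
    fx = fun(x)
    for _ in range(max_steps):
        fpp = fun(x + [h, 0.0])
        fpm = fun(x - [h, 0.0])
        fcp = fun(x + [0.0, h])
        fcm = fun(x - [0.0, h])
        g = np.array([(fpp - fpm) / (2 * h), (fcp - fcm) / (2 * h)])
        hrr = (fpp - 2 * fx + fpm) / h**2
        hcc = (fcp - 2 * fx + fcm) / h**2
        hrc = (
            fun(x + [h, h]) - fun(x + [h, -h]) - fun(x + [-h, h]) + fun(x + [-h, -h])
        ) / (4 * h**2)
        H = np.array([[hrr, hrc], [hrc, hcc]])
        if np.linalg.det(H) <= 0:
            break
        step = np.linalg.solve(H, -g)
        x_new = x + step
        f_new = fun(x_new)
        if not np.isfinite(f_new) or f_new >= fx:
            break
        x, fx = x_new, f_new
        if np.max(np.abs(step)) < 1e-12:
            break
    return x, fx


def estimate_delays(
    window: AnalysisWindow,
    weights: ChannelWeights | None = None,
    search_cfg: SearchConfig | None = None,
    init: DelayPair | None = None,
) -> DelayPair:
    """Maximum-likelihood estimate of the (tau_r, tau_c) delay pair.

    Two stages: (i) coarse exhaustive search of the concentrated cost
    over +-tau_max at half-sample resolution (skipped when ``init`` is
    supplied), then (ii) continuous local minimization of the
    concentrated cost -- the reference shape is re-estimated in closed
    form at every candidate delay pair, so the search converges directly
    to the joint (shape, delays) optimum with sub-sample resolution.
    ``converged`` is False if the simplex search exhausted its iteration
    budget before reaching ``tol_s``.
    """
    cfg = search_cfg or SearchConfig()
    seg = window.grid_segment
    n_rows, n_cols, n = seg.shape
    if n / window.fs_hz < 1.0:
        raise ValueError("window must be at least 1 s long")
    w = _resolve_weights(weights, n_rows, n_cols)
    live_rows = np.count_nonzero(w.sum(axis=1) > 0)
    live_cols = np.count_nonzero(w.sum(axis=0) > 0)
    if live_rows < 2 or live_cols < 2:
        raise ValueError("need at least 2 live rows and 2 live columns")

    step = cfg.coarse_step_s if cfg.coarse_step_s is not None else 0.5 / window.fs_hz
    if init is not None:
        tau = np.array([init.tau_r_s, init.tau_c_s])
    else:
        tau = np.array(_coarse_search(seg, window.fs_hz, w, cfg.tau_max_s, step))

    X = rfft(seg, axis=2)
    freqs = rfftfreq(n, d=1.0 / window.fs_hz)
    pw = _parseval_bin_weights(n)
    per_channel_power = np.tensordot(np.abs(X) ** 2, pw, axes=([2], [0])) / n
    const = float(np.sum(w * per_channel_power))

    xatol = max(cfg.tol_s * 1e-3, 1e-9)
    f0 = _concentrated_cost(X, freqs, tau[0], tau[1], w, pw, n, const)
    res = optimize.minimize(
        lambda p: _concentrated_cost(X, freqs, p[0], p[1], w, pw, n, const),
        tau,
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            # relative fatol: an absolute zero is unattainable in floating
            # point and can keep the simplex jittering at maxiter
            "fatol": 1e-12 * max(abs(f0), abs(const), np.finfo(float).tiny),
            "maxiter": 200 * cfg.max_iter,
            "initial_simplex": np.array(
                [tau, tau + [step, 0.0], tau + [0.0, step]]
            ),
        },
    )
    tau, cost = _newton_polish(
        lambda p: _concentrated_cost(X, freqs, p[0], p[1], w, pw, n, const), res.x
    )
    cost = float(cost)
    return DelayPair(
        tau_r_s=float(tau[0]),
        tau_c_s=float(tau[1]),
        cost=max(cost, 0.0),
        converged=bool(res.success),
    )


def delays_to_cv(
    delays: DelayPair, electrode_spacing_cm: float, window_ref: str = ""
) -> CVVector:
    """Invert the delay pair into a CV amplitude and incidence angle.

    CV = d / sqrt(tau_r^2 + tau_c^2); theta = atan2(tau_c, tau_r), in
    [-pi, pi] from the grid's vertical (row) axis.  A zero delay vector
    would imply infinite velocity and yields an excluded vector.
    """
    if electrode_spacing_cm <= 0:
        raise ValueError("electrode_spacing_cm must be positive")
    norm = math.hypot(delays.tau_r_s, delays.tau_c_s)
    if norm == 0.0:
        return CVVector(
            amplitude_cm_s=math.inf,
            angle_rad=0.0,
            window_ref=window_ref,
            excluded=True,
            reason="zero-delay",
        )
    return CVVector(
        amplitude_cm_s=electrode_spacing_cm / norm,
        angle_rad=math.atan2(delays.tau_c_s, delays.tau_r_s),
        window_ref=window_ref,
    )


def filter_outliers(
    cvs: list[CVVector], max_cv_cm_s: float = MAX_PHYSIOLOGICAL_CV_CM_S
) -> list[CVVector]:
    """Mark CV vectors strictly above ``max_cv_cm_s`` as excluded.

    Values above 30 cm/s are far outside the physiological range and are
    treated as non-propagating artifacts; exactly 30 cm/s is retained.
    Order is preserved and retained vectors are untouched.
    """
    out: list[CVVector] = []
    for v in cvs:
        if not v.excluded and v.amplitude_cm_s > max_cv_cm_s:
            out.append(
                CVVector(
                    amplitude_cm_s=v.amplitude_cm_s,
                    angle_rad=v.angle_rad,
                    window_ref=v.window_ref,
                    excluded=True,
                    reason="supra-physiological",
                )
            )
        else:
            out.append(v)
    return out


def estimate_contraction_cv(
    recording: GridRecording,
    contraction: ContractionSegment,
    window_length_s: float = 10.0,
    overlap_s: float = 5.0,
    f_band_hz: tuple[float, float] | None = (0.3, 5.0),
    search_cfg: SearchConfig | None = None,
    max_cv_cm_s: float = MAX_PHYSIOLOGICAL_CV_CM_S,
    refine_weights: bool = True,
) -> list[tuple[AnalysisWindow, DelayPair, CVVector]]:
    """Full per-contraction CV pipeline.

    Band-passes the grid, cuts the contraction into overlapping windows,
    estimates channel weights (high-frequency noise floor from the raw
    segment, optionally refined from the model residual), runs the ML
    delay search per window, converts delays to CV vectors, and applies
    the physiological outlier rule.  Non-converged windows are marked
    excluded.
    """
    cfg = search_cfg or SearchConfig(electrode_spacing_cm=recording.electrode_spacing_cm)
    raw_windows = segment_contraction(contraction, recording, window_length_s, overlap_s)
    if not raw_windows:
        return []
    filtered = recording.grid_signals
    if f_band_hz is not None:
        filtered = bandpass_grid(filtered, recording.fs_hz, f_band_hz)

    results: list[tuple[AnalysisWindow, DelayPair, CVVector]] = []
    cvs: list[CVVector] = []
    for win in raw_windows:
        weights = estimate_channel_weights(win)  # noise floor from raw segment
        i0 = int(round(win.start_s * recording.fs_hz))
        fwin = AnalysisWindow(
            start_s=win.start_s,
            length_s=win.length_s,
            grid_segment=filtered[:, :, i0 : i0 + win.n_samples],
            fs_hz=win.fs_hz,
            parent_contraction=win.parent_contraction,
        )
        delays = estimate_delays(fwin, weights, cfg)
        if refine_weights:
            weights = estimate_channel_weights(fwin, delays)
            delays = estimate_delays(fwin, weights, cfg, init=delays)
        ref = f"{win.parent_contraction}@{win.start_s:.1f}s"
        cv = delays_to_cv(delays, recording.electrode_spacing_cm, window_ref=ref)
        if not delays.converged and not cv.excluded:
            cv = CVVector(
                amplitude_cm_s=cv.amplitude_cm_s,
                angle_rad=cv.angle_rad,
                window_ref=ref,
                excluded=True,
                reason="non-converged",
            )
        results.append((fwin, delays, cv))
        cvs.append(cv)

    cvs = filter_outliers(cvs, max_cv_cm_s)
    return [(w, d, v) for (w, d, _), v in zip(results, cvs)]
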