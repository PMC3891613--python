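"""Independent reference computations used to check the package.

Everything here deliberately avoids the implementation's code paths:
direct DFT sums instead of rfft-based pipelines, time-domain correlation
scans instead of frequency-domain phase search, closed forms instead of
library calls.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def dft_spectral_centroid(x: np.ndarray, fs_hz: float) -> float:
    """Spectral centroid via an explicit direct DFT sum (no FFT)."""
    n = x.size
    k = np.arange(n // 2 + 1)
    # direct DFT: X_k = sum_n x_n exp(-2j pi k n / N)
    ph = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    mag2 = np.abs(ph @ x) ** 2
    freqs = k * fs_hz / n
    return float(np.sum(freqs * mag2) / np.sum(mag2))


def xcorr_peak_lag(x: np.ndarray, y: np.ndarray) -> int:
    """Lag (samples) maximizing the full cross-correlation of y against x,
    positive when y is a delayed copy of x.  Exhaustive scan over every
    lag; the direct O(n^2) sum is used for short inputs and exact FFT
    convolution for long ones."""
    if x.size <= 4096:
        corr = np.correlate(y, x, mode="full")
    else:
        corr = sps.fftconvolve(y, x[::-1], mode="full")
    return int(np.argmax(corr)) - (x.size - 1)


def upsampled_xcorr_delay(
    x: np.ndarray, y: np.ndarray, fs_hz: float, upsample: int = 20
) -> float:
    """Sub-sample delay of y relative to x from an exhaustive scan of the
    upsampled cross-correlation (resolution 1/(fs*upsample))."""
    xu = sps.resample(x, x.size * upsample)
    yu = sps.resample(y, y.size * upsample)
    lag = xcorr_peak_lag(xu, yu)
    return lag / (fs_hz * upsample)


def brute_force_delays(
    seg: np.ndarray,
    fs_hz: float,
    weights: np.ndarray,
    tau_max_s: float = 0.1,
    step_s: float = 1e-4,
) -> tuple[float, float]:
    """Exhaustive time-domain delay-pair search on a fixed grid.

    For every candidate (tau_r, tau_c) on the grid the objective is the
    weighted energy of the re-aligned channel sum, which expands into
    pairwise channel cross-correlations evaluated at lag
    (dr*tau_r + dc*tau_c).  Correlations are computed on signals
    upsampled to the grid resolution, so candidate lags are exact integer
    indices.  O(grid^2 * pairs); intended for small grids/windows only.
    """
    n_rows, n_cols, n = seg.shape
    up = int(round(1.0 / (fs_hz * step_s)))
    n_up = n * up
    segu = sps.resample(seg, n_up, axis=2)
    n_t = int(round(tau_max_s / step_s))
    a = np.arange(-n_t, n_t + 1)
    q = np.zeros((a.size, a.size))
    mid = n_up - 1
    for dr in range(n_rows):
        for dc in range(-(n_cols - 1), n_cols):
            if dr == 0 and dc <= 0:
                continue  # self terms constant; negative classes symmetric
            corr = np.zeros(2 * n_up - 1)
            for r in range(dr, n_rows):
                for c in range(max(dc, 0), n_cols + min(dc, 0)):
                    wprod = weights[r, c] * weights[r - dr, c - dc]
                    if wprod == 0:
                        continue
                    corr += wprod * sps.fftconvolve(segu[r, c], segu[r - dr, c - dc][::-1])
            lag = mid + dr * a[:, None] + dc * a[None, :]
            q += 2.0 * corr[lag]
    i, j = np.unravel_index(np.argmax(q), q.shape)
    return float(a[i] * step_s), float(a[j] * step_s)


def dft_shift_sse(
    seg: np.ndarray,
    shape_spectrum: np.ndarray,
    fs_hz: float,
    tau_r_s: float,
    tau_c_s: float,
    weights: np.ndarray,
) -> float:
    """Time-domain weighted SSE against explicitly shifted reference shapes.

    The reference waveform is reconstructed and fractionally shifted per
    channel by a direct inverse-DFT sum (explicit exponentials, no FFT),
    then compared to the channel in the time domain.
    """
    n_rows, n_cols, n = seg.shape
    k = np.arange(shape_spectrum.size)
    t = np.arange(n)
    # direct inverse DFT of a one-sided spectrum of a real signal
    basis = np.exp(2j * np.pi * np.outer(t, k) / n)
    scale = np.full(shape_spectrum.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    total = 0.0
    for r in range(n_rows):
        for c in range(n_cols):
            delay = r * tau_r_s + c * tau_c_s
            shifted_spec = shape_spectrum * np.exp(
                -2j * np.pi * (k * fs_hz / n) * delay
            )
            s_rc = (basis @ (scale * shifted_spec)).real / n
            total += weights[r, c] * float(np.sum((seg[r, c] - s_rc) ** 2))
    return total


def pooled_t_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form pooled-variance two-sample t statistic."""
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))
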