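"""Synthetic high-density EHG generator with known propagation.

Simulates the plane-wave signal model underlying 2-D conduction-velocity
estimation: every channel (r, c) of the grid records the same
action-potential shape s(n), delayed by (r-1)*tau_r + (c-1)*tau_c relative
to channel (1, 1), plus independent white Gaussian noise,

    x_rc(n) = s(n - (r-1)*tau_r - (c-1)*tau_c) + w_rc(n),

with (tau_r, tau_c) fixed by the true CV amplitude and incidence angle of
each scheduled contraction.  Action potentials occur in bursts during
contractions and are absent in between, so the generated recordings have a
usable contraction-detection surface as well: the bipolar channel carries
the burst envelope modulating 0.3-0.8 Hz band-limited activity.

Fractional (sub-sample) delays are realized exactly by frequency-domain
phase multiplication on a zero-padded buffer, so the ground-truth delays
are not quantized to the sampling grid.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import GridRecording, SimScenario, plane_wave_delays

__all__ = [
    "generate_ap_waveform",
    "fractional_shift",
    "generate_grid_recording",
    "synthesize_plane_wave_window",
    "empirical_snr_db",
]

#: Peak amplitude of a single action potential at the skin, in uV.
AP_AMPLITUDE_UV = 50.0


def generate_ap_waveform(
    fs_hz: float, duration_s: float, shape: str = "biphasic"
) -> np.ndarray:
    """Return the reference action-potential shape s(n) as a 1-D array.

    The default (and only) family is a biphasic pulse -- the first
    derivative of a Gaussian with sigma = duration/6 -- which is zero-mean,
    band-limited, and matches the gross morphology of surface-recorded
    uterine action potentials.  Peak amplitude is normalized to 1.

    Parameters
    ----------
    fs_hz : sampling rate in Hz.
    duration_s : total support of the pulse in seconds; must cover at
        least 8 samples.
    shape : waveform family tag; only ``"biphasic"`` is defined.
    """
    if fs_hz <= 0 or duration_s <= 0:
        raise ValueError("fs_hz and duration_s must be positive")
    n = int(round(duration_s * fs_hz))
    if n < 8:
        raise ValueError("pulse must span at least 8 samples")
    if shape != "biphasic":
        raise ValueError(f"unknown waveform family: {shape!r}")
    t = (np.arange(n) - (n - 1) / 2) / fs_hz
    sigma = duration_s / 6.0
    w = -t * np.exp(-(t**2) / (2.0 * sigma**2))
    w -= w.mean()  # exact zero mean despite truncation
    return w / np.max(np.abs(w))


def fractional_shift(x: np.ndarray, shift_s: float, fs_hz: float) -> np.ndarray:
    """Delay ``x`` by ``shift_s`` seconds (possibly fractional samples).

    Implemented as linear-phase multiplication in the frequency domain on
    a zero-padded copy, so the shift is exact for band-limited content and
    wrap-around leakage is pushed into the discarded padding.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    pad = int(np.ceil(abs(shift_s) * fs_hz)) + 8
    nfft = n + 2 * pad
    spec = np.fft.rfft(x, n=nfft)
    f = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    out = np.fft.irfft(spec * np.exp(-2j * np.pi * f * shift_s), n=nfft)
    return out[:n]


def _tukey_env(phase: np.ndarray, taper: float = 0.25) -> np.ndarray:
    """Tukey (tapered-cosine) contraction envelope on phase in [0, 1]:
    cosine rise over ``taper``, unit plateau, cosine fall.  Contractions
    build up, hold, and release rather than peaking instantaneously."""
    phase = np.asarray(phase, dtype=float)
    env = np.ones_like(phase)
    rise = phase < taper
    fall = phase > 1.0 - taper
    env[rise] = 0.5 * (1 - np.cos(np.pi * phase[rise] / taper))
    env[fall] = 0.5 * (1 - np.cos(np.pi * (1 - phase[fall]) / taper))
    return env


def _spike_train(
    rng: np.random.Generator,
    fs_hz: float,
    seg_len: int,
    t0_in_seg_s: float,
    usable_s: float,
    rate_hz: float,
    pulse: np.ndarray,
) -> np.ndarray:
    """Clean reference-channel burst: jittered near-regular spikes whose
    amplitudes follow a raised-cosine envelope over the burst."""
    out = np.zeros(seg_len)
    period = 1.0 / rate_hz
    n_spikes = max(1, int(np.floor(usable_s / period)))
    base = t0_in_seg_s + (np.arange(n_spikes) + 0.5) * (usable_s / n_spikes)
    jitter = rng.uniform(-0.25, 0.25, size=n_spikes) * (usable_s / n_spikes)
    times = base + jitter
    phase = (times - t0_in_seg_s) / usable_s  # 0..1 across the burst
    amps = AP_AMPLITUDE_UV * (0.3 + 0.7 * _tukey_env(np.clip(phase, 0, 1)))
    half = pulse.size // 2
    for t, a in zip(times, amps):
        i = int(round(t * fs_hz)) - half
        lo, hi = max(i, 0), min(i + pulse.size, seg_len)
        if hi > lo:
            out[lo:hi] += a * pulse[lo - i : hi - i]
    return out


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs_hz: float, lo_hz: float, hi_hz: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo_hz, hi_hz]."""
    sos = sps.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=fs_hz, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + int(20 * fs_hz)))
    x = x[int(10 * fs_hz) : int(10 * fs_hz) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_grid_recording(scenario: SimScenario) -> GridRecording:
    """Simulate a grid recording obeying the plane-wave model.

    Within each scheduled contraction, spikes on channel (r, c) are exact
    fractionally-delayed copies of channel (1, 1); between contractions
    only noise is present.  White Gaussian noise is added per channel so
    that the ratio of within-contraction clean signal power to noise power
    equals ``scenario.snr_db`` (``snr_db = inf`` gives a noiseless
    recording).  Tocodynamometer marks replicate the schedule; maternal
    perception marks are placed at contraction midpoints.
    """
    sc = scenario
    rng = np.random.default_rng(sc.rng_seed)
    fs = sc.fs_hz
    n_samples = sc.n_samples
    grid = np.zeros((sc.n_rows, sc.n_cols, n_samples))
    pulse = generate_ap_waveform(fs, sc.ap_width_s)

    clean_energy = 0.0  # summed over channels, within contractions
    contraction_samples = 0
    envelope = np.zeros(n_samples)

    for (onset, dur), cv, theta in zip(
        sc.contraction_schedule, sc.true_cv_cm_s, sc.true_angle_rad
    ):
        tau_r, tau_c = plane_wave_delays(cv, theta, sc.electrode_spacing_cm)
        shifts = np.array(
            [
                [(r * tau_r + c * tau_c) for c in range(sc.n_cols)]
                for r in range(sc.n_rows)
            ]
        )
        span = shifts.max() - shifts.min()
        if span >= dur:
            raise ValueError(
                f"grid delay span {span:.3f} s exceeds contraction duration {dur:.3f} s"
            )
        # spikes placed so every delayed copy stays inside the contraction
        lead = sc.ap_width_s / 2 + max(0.0, -shifts.min())
        trail = sc.ap_width_s / 2 + max(0.0, shifts.max())
        usable = dur - lead - trail
        if usable <= 0:
            raise ValueError("contraction too short for the requested delays")

        margin = span + sc.ap_width_s + 0.5
        seg_start = int(np.floor(max(onset - margin, 0.0) * fs))
        seg_end = int(np.ceil(min(onset + dur + margin, sc.duration_s) * fs))
        seg_len = seg_end - seg_start
        t0_in_seg = onset + lead - seg_start / fs
        source = _spike_train(rng, fs, seg_len, t0_in_seg, usable, sc.spike_rate_hz, pulse)

        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        for r in range(sc.n_rows):
            for c in range(sc.n_cols):
                delayed = fractional_shift(source, shifts[r, c], fs)
                grid[r, c, seg_start:seg_end] += delayed
                clean_energy += float(np.sum(delayed[i0 - seg_start : i1 - seg_start] ** 2))
        contraction_samples += i1 - i0
        t_env = np.arange(i0, i1) / fs
        envelope[i0:i1] = _tukey_env((t_env - onset) / dur)

    n_channels = sc.n_rows * sc.n_cols
    signal_power = clean_energy / max(contraction_samples * n_channels, 1)

    if np.isfinite(sc.snr_db):
        noise_var = signal_power * 10.0 ** (-sc.snr_db / 10.0)
        if not np.isfinite(noise_var) or noise_var < 0:
            raise ValueError("snr_db produces an invalid noise power")
        grid += rng.normal(0.0, np.sqrt(noise_var), size=grid.shape)
    else:
        noise_var = 0.0

    # Bipolar channel: difference of two virtual electrodes sharing a
    # common-mode term; the difference carries the burst envelope
    # modulating 0.3-0.8 Hz band-limited activity, plus its own noise.
    carrier = _bandlimited_noise(rng, n_samples, fs, 0.3, 0.8)
    bip_amp = np.sqrt(signal_power) if signal_power > 0 else 1.0
    common = rng.standard_normal(n_samples) * np.sqrt(noise_var)
    v1 = common + 0.5 * bip_amp * envelope * carrier
    v2 = common - 0.5 * bip_amp * envelope * carrier
    bipolar = v1 - v2
    if noise_var > 0:
        bipolar = bipolar + rng.normal(0.0, np.sqrt(noise_var), size=n_samples)

    return GridRecording(
        grid_signals=grid,
        bipolar_signal=bipolar,
        fs_hz=fs,
        electrode_spacing_cm=sc.electrode_spacing_cm,
        toco_marks=[(float(a), float(b)) for a, b in sc.contraction_schedule],
        perception_marks=[float(a + b / 2) for a, b in sc.contraction_schedule],
        ground_truth=sc,
    )


def synthesize_plane_wave_window(
    cv_cm_s: float,
    angle_rad: float,
    *,
    n_rows: int = 8,
    n_cols: int = 8,
    fs_hz: float = 200.0,
    duration_s: float = 10.0,
    electrode_spacing_cm: float = 0.5,
    snr_db: float = np.inf,
    spike_rate_hz: float = 1.5,
    ap_width_s: float = 0.3,
    rng: np.random.Generator | int | None = None,
):
    """Build a single analysis window obeying the plane-wave model exactly.

    The reference channel holds a spike burst confined to the window
    interior; every other channel is its exact fractionally-delayed copy
    (frequency-domain phase shift of the window itself), so the spectral
    relation X_rc(f) = S(f) exp(-j 2 pi f [(r-1) tau_r + (c-1) tau_c])
    holds to machine precision before noise is added.  Returns the window
    and the ground-truth delay pair.  Intended as the acceptance surface
    for delay estimators; full recordings come from
    :func:`generate_grid_recording`.
    """
    from .types import AnalysisWindow, DelayPair  # local import avoids cycle noise

    rng = np.random.default_rng(rng)
    tau_r, tau_c = plane_wave_delays(cv_cm_s, angle_rad, electrode_spacing_cm)
    n = int(round(duration_s * fs_hz))
    shifts = np.array(
        [[r * tau_r + c * tau_c for c in range(n_cols)] for r in range(n_rows)]
    )
    span = shifts.max() - shifts.min()
    margin = span + ap_width_s
    usable = duration_s - 2 * margin
    if usable <= 1.0 / spike_rate_hz:
        raise ValueError("window too short for the requested delays and spike rate")

    pulse = generate_ap_waveform(fs_hz, ap_width_s)
    source = _spike_train(rng, fs_hz, n, margin, usable, spike_rate_hz, pulse)

    spec = np.fft.rfft(source)
    if n % 2 == 0:
        # the model is band-limited; a populated Nyquist bin cannot carry a
        # fractional phase shift through irfft (which forces it real)
        spec[-1] = 0.0
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    grid = np.empty((n_rows, n_cols, n))
    for r in range(n_rows):
        for c in range(n_cols):
            grid[r, c] = np.fft.irfft(spec * np.exp(-2j * np.pi * f * shifts[r, c]), n=n)

    if np.isfinite(snr_db):
        p_sig = float(np.mean(grid**2))
        noise_sd = np.sqrt(p_sig * 10.0 ** (-snr_db / 10.0))
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)

    window = AnalysisWindow(
        start_s=0.0, length_s=duration_s, grid_segment=grid, fs_hz=fs_hz
    )
    return window, DelayPair(tau_r_s=tau_r, tau_c_s=tau_c)


def empirical_snr_db(recording: GridRecording) -> float:
    """Measured SNR of a synthetic recording, averaged over grid channels.

    Noise power is estimated from the inter-contraction (signal-free)
    samples; signal power as the within-contraction excess power over that
    noise floor.  Requires ground truth for the contraction schedule.
    """
    sc = recording.ground_truth
    if sc is None:
        raise ValueError("empirical SNR requires a recording with ground truth")
    fs = recording.fs_hz
    mask = np.zeros(recording.n_samples, dtype=bool)
    for onset, dur in sc.contraction_schedule:
        mask[int(round(onset * fs)) : int(round((onset + dur) * fs))] = True
    flat = recording.grid_signals.reshape(-1, recording.n_samples)
    noise_power = np.mean(flat[:, ~mask] ** 2, axis=1)
    total_power = np.mean(flat[:, mask] ** 2, axis=1)
    sig = np.maximum(total_power - noise_power, 1e-300)
    return float(10.0 * np.log10(np.mean(sig) / np.mean(noise_power)))
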