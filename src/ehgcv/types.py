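"""Domain containers for EHG conduction-velocity analysis.

The central objects mirror the physical experiment: an 8x8 monopolar
high-density electrode grid over the abdomen plus one bipolar pair, a
contraction timeline, and per-window two-dimensional conduction-velocity
(CV) vectors.  Angles are measured from the grid's vertical (row) axis,
positive counter-clockwise, in [-pi, pi]; rows increase downward (toward
the cervix as the grid is mounted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimScenario",
    "GridRecording",
    "Spectrogram",
    "IUPEstimate",
    "ContractionSegment",
    "AnalysisWindow",
    "DelayPair",
    "CVVector",
    "ChannelWeights",
    "ReferenceShape",
    "PatientRecord",
    "GroupComparison",
]


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth description of a synthetic grid recording.

    Each scheduled contraction carries its own true CV amplitude (cm/s)
    and incidence angle theta (rad, from the vertical/row axis), which
    together fix the inter-row and inter-column delays of the simulated
    plane wave.
    """

    electrode_spacing_cm: float = 0.5
    fs_hz: float = 200.0
    duration_s: float = 120.0
    n_rows: int = 8
    n_cols: int = 8
    contraction_schedule: tuple[tuple[float, float], ...] = ((40.0, 40.0),)
    true_cv_cm_s: tuple[float, ...] = (10.0,)
    true_angle_rad: tuple[float, ...] = (0.0,)
    spike_rate_hz: float = 1.5
    snr_db: float = 10.0
    ap_width_s: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if self.electrode_spacing_cm <= 0:
            raise ValueError("electrode_spacing_cm must be positive")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fs_hz and duration_s must be positive")
        if self.spike_rate_hz <= 0 or self.ap_width_s <= 0:
            raise ValueError("spike_rate_hz and ap_width_s must be positive")
        sched = tuple((float(a), float(b)) for a, b in self.contraction_schedule)
        if len(self.true_cv_cm_s) != len(sched) or len(self.true_angle_rad) != len(sched):
            raise ValueError("one CV and one angle required per scheduled contraction")
        prev_end = -math.inf
        for onset, dur in sched:
            if dur <= 0 or onset < 0 or onset + dur > self.duration_s:
                raise ValueError("contractions must lie within [0, duration_s]")
            if onset < prev_end:
                raise ValueError("contractions must not overlap")
            prev_end = onset + dur
        for cv in self.true_cv_cm_s:
            if cv <= 0:
                raise ValueError("true_cv_cm_s must be positive")
        for th in self.true_angle_rad:
            if not -math.pi <= th <= math.pi:
                raise ValueError("true_angle_rad must lie in [-pi, pi]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class GridRecording:
    """Multichannel recording: (n_rows, n_cols, n_samples) grid in uV plus
    one bipolar channel used only for contraction timing."""

    grid_signals: np.ndarray
    bipolar_signal: np.ndarray
    fs_hz: float
    electrode_spacing_cm: float
    toco_marks: list[tuple[float, float]] = field(default_factory=list)
    perception_marks: list[float] = field(default_factory=list)
    ground_truth: SimScenario | None = None

    def __post_init__(self) -> None:
        self.grid_signals = np.asarray(self.grid_signals, dtype=float)
        self.bipolar_signal = np.asarray(self.bipolar_signal, dtype=float)
        if self.grid_signals.ndim != 3:
            raise ValueError("grid_signals must have shape (n_rows, n_cols, n_samples)")
        if self.fs_hz <= 0 or self.electrode_spacing_cm <= 0:
            raise ValueError("fs_hz and electrode_spacing_cm must be positive")

    @property
    def n_rows(self) -> int:
        return self.grid_signals.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid_signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.grid_signals.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class Spectrogram:
    """Short-time power spectral estimate rho(n, f) of one channel."""

    power: np.ndarray  # (n_frames, n_freqs), >= 0
    frame_times_s: np.ndarray
    freqs_hz: np.ndarray
    frame_hop_s: float

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be nonnegative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")


@dataclass
class IUPEstimate:
    """Estimated intrauterine pressure surrogate Psi(n): the unnormalized
    first spectral moment of the bipolar spectrogram over [f_min, f_max]."""

    psi: np.ndarray
    frame_times_s: np.ndarray
    f_min_hz: float = 0.3
    f_max_hz: float = 0.8

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.f_min_hz >= self.f_max_hz:
            raise ValueError("f_min_hz must be below f_max_hz")
        if np.any(self.psi < 0):
            raise ValueError("psi must be nonnegative")


@dataclass
class ContractionSegment:
    onset_s: float
    duration_s: float
    peak_psi: float = 0.0
    confirmed_by: frozenset[str] = frozenset()
    source_recording: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.onset_s < 0:
            raise ValueError("onset_s must be nonnegative")
        self.confirmed_by = frozenset(self.confirmed_by)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnalysisWindow:
    """One delay-estimation segment of a contraction."""

    start_s: float
    length_s: float
    grid_segment: np.ndarray  # (n_rows, n_cols, samples)
    fs_hz: float
    parent_contraction: str = ""

    def __post_init__(self) -> None:
        self.grid_segment = np.asarray(self.grid_segment, dtype=float)
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if self.grid_segment.ndim != 3:
            raise ValueError("grid_segment must be (n_rows, n_cols, samples)")

    @property
    def n_samples(self) -> int:
        return self.grid_segment.shape[2]


@dataclass
class DelayPair:
    """Inter-row / inter-column delay estimate (seconds) with the value of
    the weighted spectral cost E^2 at the optimum."""

    tau_r_s: float
    tau_c_s: float
    cost: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be nonnegative")


@dataclass
class CVVector:
    """2-D conduction-velocity vector: amplitude (cm/s) and incidence
    angle from the vertical (row) axis."""

    amplitude_cm_s: float
    angle_rad: float
    window_ref: str = ""
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.excluded and self.amplitude_cm_s <= 0:
            raise ValueError("amplitude_cm_s must be positive unless excluded")
        if np.isfinite(self.angle_rad) and not -math.pi <= self.angle_rad <= math.pi + 1e-12:
            raise ValueError("angle_rad must lie in [-pi, pi]")

    @property
    def components_cm_s(self) -> tuple[float, float]:
        """Cartesian components (row-axis, column-axis)."""
        return (
            self.amplitude_cm_s * math.cos(self.angle_rad),
            self.amplitude_cm_s * math.sin(self.angle_rad),
        )


@dataclass
class ChannelWeights:
    """Per-channel weights, inversely proportional to estimated channel
    noise, normalized to mean 1 over live channels."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and nonnegative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one channel weight must be positive")


@dataclass
class ReferenceShape:
    """One-sided spectrum S(f) of the common action-potential shape."""

    spectrum: np.ndarray  # complex, rfft layout (n_samples//2 + 1 bins)
    n_samples: int

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=complex)
        if not np.all(np.isfinite(self.spectrum)):
            raise ValueError("reference spectrum must be finite")

    def waveform(self) -> np.ndarray:
        return np.fft.irfft(self.spectrum, n=self.n_samples)


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # "labor" | "nonlabor"
    contraction_cvs: list[CVVector] = field(default_factory=list)
    patient_cv: CVVector | None = None

    def __post_init__(self) -> None:
        if self.group not in ("labor", "nonlabor"):
            raise ValueError("group must be 'labor' or 'nonlabor'")


@dataclass
class GroupComparison:
    labor_mean_cm_s: float
    labor_sd_cm_s: float
    nonlabor_mean_cm_s: float
    nonlabor_sd_cm_s: float
    shapiro_p_labor: float
    shapiro_p_nonlabor: float
    levene_p: float
    ttest_p: float
    alpha: float = 0.05
    significant: bool = False
    n_labor: int = 0
    n_nonlabor: int = 0

    def __post_init__(self) -> None:
        for p in (self.shapiro_p_labor, self.shapiro_p_nonlabor, self.levene_p, self.ttest_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


def classify_group(hours_to_delivery: float) -> str:
    """Labor group iff delivery occurred within 24 h of the measurement."""
    return "labor" if hours_to_delivery <= 24.0 else "nonlabor"


def wrap_angle(theta: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle to [-pi, pi]."""
    return np.arctan2(np.sin(theta), np.cos(theta))


def plane_wave_delays(
    cv_cm_s: float, angle_rad: float, electrode_spacing_cm: float
) -> tuple[float, float]:
    """Forward map from a CV vector to (tau_r, tau_c) in seconds.

    tau_r = d cos(theta)/CV, tau_c = d sin(theta)/CV: the arrival delay
    between adjacent rows and adjacent columns of a plane wave of speed
    CV hitting the grid at incidence angle theta.
    """
    if cv_cm_s <= 0:
        raise ValueError("cv_cm_s must be positive")
    if electrode_spacing_cm <= 0:
        raise ValueError("electrode_spacing_cm must be positive")
    return (
        electrode_spacing_cm * math.cos(angle_rad) / cv_cm_s,
        electrode_spacing_cm * math.sin(angle_rad) / cv_cm_s,
    )
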