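"""Aggregation of window-level CV vectors and labor vs. nonlabor comparison.

Window vectors are averaged to one vector per contraction, contraction
vectors to one per patient, so the group comparison is independent of how
many windows or contractions each patient contributed.  "Average CV
vector" is implemented as a true vector (Cartesian-component) mean; a
scalar mean of the amplitudes is computed alongside, and either can feed
the group test.  Groups (labor = delivery within 24 h of the measurement)
are compared on per-patient CV amplitude with Shapiro-Wilk normality
checks per group, Levene's test for equal variances, and a two-sided
independent-samples t-test at alpha = 0.05.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sstats

from .types import CVVector, GroupComparison, PatientRecord

__all__ = [
    "average_contraction",
    "average_patient",
    "scalar_mean_amplitude",
    "circular_variance",
    "compare_groups",
]


def _vector_mean(vectors: list[CVVector], level: str) -> CVVector:
    used = [v for v in vectors if not v.excluded]
    if not used:
        raise ValueError(f"no usable CV vectors to average at {level} level")
    x = float(np.mean([v.components_cm_s[0] for v in used]))
    y = float(np.mean([v.components_cm_s[1] for v in used]))
    amp = math.hypot(x, y)
    scale = max(max(v.amplitude_cm_s for v in used), np.finfo(float).tiny)
    if amp <= 1e-9 * scale:
        # opposing directions cancelled; no meaningful mean direction
        return CVVector(
            amplitude_cm_s=amp, angle_rad=0.0, excluded=True, reason="degenerate-mean"
        )
    return CVVector(amplitude_cm_s=amp, angle_rad=math.atan2(y, x))


def average_contraction(windows: list[CVVector]) -> CVVector:
    """Vector mean of the non-excluded window vectors of one contraction.

    Cartesian components (CV cos(theta), CV sin(theta)) are averaged and
    converted back to (amplitude, angle).  Fully cancelling directions
    yield a degenerate (excluded) vector.  Raises if no window survived
    exclusion -- callers drop such contractions.
    """
    return _vector_mean(windows, "contraction")


def average_patient(contractions: list[CVVector]) -> CVVector:
    """Vector mean of a patient's per-contraction vectors (same contract
    as :func:`average_contraction`, one level up)."""
    return _vector_mean(contractions, "patient")


def scalar_mean_amplitude(vectors: list[CVVector]) -> float:
    """Plain mean of non-excluded CV amplitudes, ignoring direction."""
    used = [v.amplitude_cm_s for v in vectors if not v.excluded]
    if not used:
        raise ValueError("no usable CV vectors")
    return float(np.mean(used))


def circular_variance(vectors: list[CVVector]) -> float:
    """Circular variance (1 - mean resultant length) of the propagation
    angles; 0 for perfectly aligned directions, up to 1 when dispersed.
    Reported descriptively -- angle variability across patients is high
    and no directional hypothesis is tested."""
    angles = np.array([v.angle_rad for v in vectors if not v.excluded])
    if angles.size == 0:
        raise ValueError("no usable CV vectors")
    return float(1.0 - np.abs(np.mean(np.exp(1j * angles))))


def compare_groups(
    patients: list[PatientRecord],
    alpha: float = 0.05,
    use_vector_mean: bool = True,
) -> GroupComparison:
    """Labor vs. nonlabor comparison of per-patient CV amplitude.

    Per-patient amplitudes are taken from ``patient_cv`` (vector-mean
    amplitude) or, with ``use_vector_mean=False``, as the scalar mean of
    the patient's contraction amplitudes.  Shapiro-Wilk runs per group,
    Levene across groups, then a two-sided independent-samples t-test
    (pooled variance); ``significant`` is ``ttest_p < alpha``.
    """
    amps: dict[str, list[float]] = {"labor": [], "nonlabor": []}
    for p in patients:
        if use_vector_mean:
            if p.patient_cv is None:
                raise ValueError(f"patient {p.patient_id} has no aggregated CV")
            amps[p.group].append(p.patient_cv.amplitude_cm_s)
        else:
            amps[p.group].append(scalar_mean_amplitude(p.contraction_cvs))
    labor = np.array(amps["labor"])
    nonlabor = np.array(amps["nonlabor"])
    if labor.size < 2 or nonlabor.size < 2:
        raise ValueError("each group needs at least 2 patients")

    # Shapiro-Wilk is undefined below 3 samples; normality is then
    # unassessable and reported as non-significant
    sw_l = sstats.shapiro(labor).pvalue if labor.size >= 3 else 1.0
    sw_n = sstats.shapiro(nonlabor).pvalue if nonlabor.size >= 3 else 1.0
    lev = sstats.levene(labor, nonlabor).pvalue
    tt = sstats.ttest_ind(labor, nonlabor, equal_var=True).pvalue

    return GroupComparison(
        labor_mean_cm_s=float(labor.mean()),
        labor_sd_cm_s=float(labor.std(ddof=1)),
        nonlabor_mean_cm_s=float(nonlabor.mean()),
        nonlabor_sd_cm_s=float(nonlabor.std(ddof=1)),
        shapiro_p_labor=float(sw_l),
        shapiro_p_nonlabor=float(sw_n),
        levene_p=float(lev),
        ttest_p=float(tt),
        alpha=alpha,
        significant=bool(tt < alpha),
        n_labor=int(labor.size),
        n_nonlabor=int(nonlabor.size),
    )
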