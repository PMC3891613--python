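"""Orchestration: simulate -> detect -> estimate -> compare as one run.

A single validated JSON config drives every stage; a run report records
per-stage record counts, dropped-record reasons, output paths, the config
hash, and the seed, so any result can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cv as cvmod
from . import detect as detmod
from . import io as iomod
from . import stats as statmod
from .synthetic import generate_grid_recording
from .types import (
    ContractionSegment,
    CVVector,
    GridRecording,
    PatientRecord,
    SimScenario,
    classify_group,
    wrap_angle,
)

__all__ = [
    "DetectConfig",
    "CVConfig",
    "StatsConfig",
    "ScenarioConfig",
    "PatientSpec",
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "make_fixture",
    "analyze_recording",
    "FIXTURE_PRESETS",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class DetectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stft_window_s: float = Field(20.0, gt=0)
    stft_hop_s: float = Field(5.0, gt=0)
    f_min_hz: float = Field(0.3, gt=0)
    f_max_hz: float = Field(0.8, gt=0)
    threshold_window_s: float = Field(60.0, gt=0)
    min_duration_s: float = Field(20.0, gt=0)
    k_sigma: float = Field(3.0, gt=0)
    perception_slack_s: float = Field(30.0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.stft_hop_s > self.stft_window_s:
            raise ValueError("stft_hop_s must not exceed stft_window_s")
        if self.f_min_hz >= self.f_max_hz:
            raise ValueError("f_min_hz must be below f_max_hz")
        return self


class CVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_length_s: float = Field(10.0, gt=0)
    overlap_s: float = Field(5.0, ge=0)
    f_band_hz: tuple[float, float] = (0.3, 5.0)
    cv_min_cm_s: float = Field(1.0, gt=0)
    cv_max_cm_s: float = Field(30.0, gt=0)
    max_iter: int = Field(20, ge=1)
    tol_s: float = Field(1e-5, gt=0)
    electrode_spacing_cm: float = Field(0.5, gt=0)
    refine_weights: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.overlap_s >= self.window_length_s:
            raise ValueError("overlap_s must be smaller than window_length_s")
        if self.f_band_hz[0] >= self.f_band_hz[1]:
            raise ValueError("f_band_hz must be an increasing pair")
        if self.cv_min_cm_s >= self.cv_max_cm_s:
            raise ValueError("cv_min_cm_s must be below cv_max_cm_s")
        return self

    def search_cfg(self) -> cvmod.SearchConfig:
        return cvmod.SearchConfig(
            electrode_spacing_cm=self.electrode_spacing_cm,
            cv_min_cm_s=self.cv_min_cm_s,
            max_iter=self.max_iter,
            tol_s=self.tol_s,
        )


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.05, gt=0, lt=1)
    use_vector_mean: bool = True


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rows: int = Field(8, ge=2)
    n_cols: int = Field(8, ge=2)
    electrode_spacing_cm: float = Field(0.5, gt=0)
    fs_hz: float = Field(200.0, gt=0)
    duration_s: float = Field(120.0, gt=0)
    contraction_schedule: list[tuple[float, float]] = [(40.0, 40.0)]
    true_cv_cm_s: list[float] = [10.0]
    true_angle_rad: list[float] = [0.0]
    spike_rate_hz: float = Field(1.5, gt=0)
    snr_db: Optional[float] = 10.0  # None = noiseless
    ap_width_s: float = Field(0.3, gt=0)

    def to_scenario(self, rng_seed: int) -> SimScenario:
        return SimScenario(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            electrode_spacing_cm=self.electrode_spacing_cm,
            fs_hz=self.fs_hz,
            duration_s=self.duration_s,
            contraction_schedule=tuple(tuple(x) for x in self.contraction_schedule),
            true_cv_cm_s=tuple(self.true_cv_cm_s),
            true_angle_rad=tuple(self.true_angle_rad),
            spike_rate_hz=self.spike_rate_hz,
            snr_db=math.inf if self.snr_db is None else self.snr_db,
            ap_width_s=self.ap_width_s,
            rng_seed=rng_seed,
        )


class PatientSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    patient_id: str
    hours_to_delivery: float = Field(gt=0)
    recording: Optional[str] = None  # path to an existing recording
    scenario: Optional[ScenarioConfig] = None

    @model_validator(mode="after")
    def _check(self):
        if (self.recording is None) == (self.scenario is None):
            raise ValueError("give exactly one of 'recording' or 'scenario'")
        return self


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rng_seed: int = 0
    out_dir: str = "ehgcv_run"
    patients: list[PatientSpec]
    detect: DetectConfig = DetectConfig()
    cv: CVConfig = CVConfig()
    stats: StatsConfig = StatsConfig()


def analyze_recording(
    recording: GridRecording,
    detect_cfg: DetectConfig | None = None,
    cv_cfg: CVConfig | None = None,
) -> tuple[list[ContractionSegment], list[tuple[str, float, object, CVVector]], list[CVVector]]:
    """Detect, confirm, and CV-analyze one recording.

    Returns (confirmed contractions, per-window result rows, one vector
    mean per contraction that produced at least one usable window).
    """
    dcfg = detect_cfg or DetectConfig()
    ccfg = cv_cfg or CVConfig(electrode_spacing_cm=recording.electrode_spacing_cm)

    spec = detmod.compute_spectrogram(
        recording.bipolar_signal, recording.fs_hz, dcfg.stft_window_s, dcfg.stft_hop_s
    )
    iup = detmod.estimate_iup(spec, dcfg.f_min_hz, dcfg.f_max_hz)
    segments = detmod.detect_contractions(
        iup,
        window_s=dcfg.threshold_window_s,
        min_duration_s=dcfg.min_duration_s,
        k_sigma=dcfg.k_sigma,
    )
    confirmed = detmod.confirm_contractions(
        segments,
        recording.toco_marks,
        recording.perception_marks,
        perception_slack_s=dcfg.perception_slack_s,
    )

    window_rows: list[tuple[str, float, object, CVVector]] = []
    contraction_cvs: list[CVVector] = []
    for i, seg in enumerate(confirmed):
        results = cvmod.estimate_contraction_cv(
            recording,
            seg,
            window_length_s=ccfg.window_length_s,
            overlap_s=ccfg.overlap_s,
            f_band_hz=ccfg.f_band_hz,
            search_cfg=ccfg.search_cfg(),
            max_cv_cm_s=ccfg.cv_max_cm_s,
            refine_weights=ccfg.refine_weights,
        )
        cid = f"c{i:02d}"
        used: list[CVVector] = []
        for win, delays, vec in results:
            window_rows.append((cid, win.start_s, delays, vec))
            used.append(vec)
        if any(not v.excluded for v in used):
            contraction_cvs.append(statmod.average_contraction(used))
    return confirmed, window_rows, contraction_cvs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study described by ``config`` and return the report.

    Deterministic for a fixed ``rng_seed``.  Partial results are written
    as each stage finishes, so they survive a later stage failure; a
    failing stage raises :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    report: dict = {
        "seed": config.rng_seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    seeds = np.random.SeedSequence(config.rng_seed).spawn(len(config.patients))

    patients: list[PatientRecord] = []
    all_contractions = []
    all_window_rows = []
    n_detected = n_confirmed = n_windows = n_excluded = 0
    dropped: list[str] = []

    for spec_p, seed in zip(config.patients, seeds):
        stage = f"input[{spec_p.patient_id}]"
        try:
            if spec_p.scenario is not None:
                scenario = spec_p.scenario.to_scenario(int(seed.generate_state(1)[0] % 2**31))
                rec = generate_grid_recording(scenario)
            else:
                rec = iomod.read_recording(spec_p.recording)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        try:
            confirmed, window_rows, contraction_cvs = analyze_recording(
                rec, config.detect, config.cv
            )
        except Exception as exc:
            raise StageError(f"analyze[{spec_p.patient_id}]", exc) from exc

        n_detected += len(confirmed)
        n_confirmed += len(confirmed)
        n_windows += len(window_rows)
        n_excluded += sum(1 for *_, v in window_rows if v.excluded)
        for seg in confirmed:
            all_contractions.append((spec_p.patient_id, seg))
        for row in window_rows:
            all_window_rows.append((f"{spec_p.patient_id}:{row[0]}", *row[1:]))

        record = PatientRecord(
            patient_id=spec_p.patient_id,
            group=classify_group(spec_p.hours_to_delivery),
            contraction_cvs=contraction_cvs,
        )
        if contraction_cvs:
            record.patient_cv = statmod.average_patient(contraction_cvs)
            patients.append(record)
        else:
            dropped.append(f"{spec_p.patient_id}: no usable contraction CV")

    # persist partial results before statistics
    contractions_csv = out / "contractions.csv"
    iomod.write_contractions_csv([s for _, s in all_contractions], contractions_csv)
    cv_csv = out / "cv_windows.csv"
    iomod.write_cv_windows_csv(all_window_rows, cv_csv)
    report["outputs"]["contractions_csv"] = str(contractions_csv)
    report["outputs"]["cv_windows_csv"] = str(cv_csv)
    report["stages"]["detect"] = {"confirmed_contractions": n_confirmed}
    report["stages"]["estimate"] = {
        "windows": n_windows,
        "windows_excluded": n_excluded,
        "windows_kept": n_windows - n_excluded,
    }
    report["stages"]["aggregate"] = {
        "patients_in": len(config.patients),
        "patients_kept": len(patients),
        "dropped": dropped,
    }

    groups = {p.group for p in patients}
    if groups == {"labor", "nonlabor"}:
        try:
            comparison = statmod.compare_groups(
                patients,
                alpha=config.stats.alpha,
                use_vector_mean=config.stats.use_vector_mean,
            )
        except Exception as exc:
            raise StageError("compare", exc) from exc
        report["comparison"] = comparison.__dict__
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, default=str))
        report["outputs"]["report_json"] = str(report_path)
    else:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))

    report["patients"] = {
        p.patient_id: {
            "group": p.group,
            "cv_cm_s": p.patient_cv.amplitude_cm_s if p.patient_cv else None,
            "angle_rad": p.patient_cv.angle_rad if p.patient_cv else None,
        }
        for p in patients
    }
    return report


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_PRESETS = ("labor-like", "nonlabor-like", "noiseless-unit")


def _preset_scenario(name: str, seed: int) -> SimScenario:
    rng = np.random.default_rng(seed)
    if name == "noiseless-unit":
        return SimScenario(
            duration_s=120.0,
            contraction_schedule=((40.0, 40.0),),
            true_cv_cm_s=(10.0,),
            true_angle_rad=(0.0,),
            snr_db=math.inf,
            rng_seed=seed,
        )
    if name in ("labor-like", "nonlabor-like"):
        mean, sd = (8.65, 1.90) if name == "labor-like" else (5.30, 1.47)
        patient_cv = float(np.clip(rng.normal(mean, sd), 2.5, 28.0))
        schedule = ((50.0, 40.0), (170.0, 40.0), (290.0, 40.0))
        cvs = tuple(
            float(np.clip(patient_cv + rng.normal(0.0, 0.3), 2.0, 29.0))
            for _ in schedule
        )
        # one coherent propagation direction per patient, jittered between
        # contractions -- directions vary across patients, not within one
        patient_angle = rng.uniform(-np.pi, np.pi)
        angles = tuple(
            float(wrap_angle(patient_angle + rng.normal(0.0, 0.2))) for _ in schedule
        )
        return SimScenario(
            duration_s=380.0,
            contraction_schedule=schedule,
            true_cv_cm_s=cvs,
            true_angle_rad=angles,
            snr_db=10.0,
            rng_seed=seed,
        )
    raise ValueError(f"unknown fixture preset: {name!r}")


def make_fixture(name: str, seed: int, out_dir: str | Path | None = None):
    """Generate a preset synthetic recording (and optionally write it).

    Presets: ``labor-like`` (per-patient CV drawn near 8.65 cm/s),
    ``nonlabor-like`` (near 5.30 cm/s), ``noiseless-unit`` (one noiseless
    contraction at 10 cm/s straight down the grid).
    """
    scenario = _preset_scenario(name, seed)
    rec = generate_grid_recording(scenario)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        iomod.write_recording(rec, out_dir / f"{name}-{seed}.tsv")
    return rec
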