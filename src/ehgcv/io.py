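"""Reading and writing recordings, annotations, and result tables.

The native on-disk recording format is plain text: a tab-separated table
with one column per channel (grid channels labelled ``R{r}C{c}``, the
bipolar channel ``BIP``) and a JSON sidecar (same stem, ``.json``)
holding the sampling rate, interelectrode distance, annotations, and --
for synthetic data -- the ground-truth scenario.  EDF/BDF recordings with
the same channel-label convention can be read when ``mne`` is installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ContractionSegment, CVVector, DelayPair, GridRecording, SimScenario

__all__ = [
    "write_recording",
    "read_recording",
    "read_annotations",
    "write_contractions_csv",
    "read_contractions_csv",
    "write_cv_windows_csv",
    "read_cv_windows_csv",
    "read_patients_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: GridRecording, path: str | Path) -> Path:
    """Write a recording as channel-per-column TSV plus a JSON sidecar."""
    path = Path(path)
    labels = [
        f"R{r + 1}C{c + 1}"
        for r in range(recording.n_rows)
        for c in range(recording.n_cols)
    ] + ["BIP"]
    data = np.column_stack(
        [recording.grid_signals.reshape(-1, recording.n_samples).T, recording.bipolar_signal]
    )
    df = pd.DataFrame(data, columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    meta: dict = {
        "fs_hz": recording.fs_hz,
        "electrode_spacing_cm": recording.electrode_spacing_cm,
        "n_rows": recording.n_rows,
        "n_cols": recording.n_cols,
        "toco": [list(m) for m in recording.toco_marks],
        "perception": list(recording.perception_marks),
    }
    if recording.ground_truth is not None:
        gt = dataclasses.asdict(recording.ground_truth)
        gt["snr_db"] = None if np.isinf(gt["snr_db"]) else gt["snr_db"]
        meta["ground_truth"] = gt
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _scenario_from_dict(d: dict) -> SimScenario:
    d = dict(d)
    if d.get("snr_db") is None:
        d["snr_db"] = np.inf
    d["contraction_schedule"] = tuple(tuple(x) for x in d["contraction_schedule"])
    for key in ("true_cv_cm_s", "true_angle_rad"):
        d[key] = tuple(d[key])
    return SimScenario(**d)


def read_annotations(path: str | Path) -> dict:
    """Load an annotation sidecar: {"toco": [[onset, duration], ...],
    "perception": [t, ...]} plus optional recording metadata."""
    meta = json.loads(Path(path).read_text())
    meta.setdefault("toco", [])
    meta.setdefault("perception", [])
    return meta


def read_recording(path: str | Path, annotations: str | Path | None = None) -> GridRecording:
    """Read a recording from native TSV or from EDF/BDF.

    Grid channels are identified by their ``R{r}C{c}`` labels; metadata
    and annotations come from the JSON sidecar (or an explicit
    ``annotations`` path, which takes precedence).
    """
    path = Path(path)
    side = Path(annotations) if annotations is not None else _sidecar_path(path)
    meta = read_annotations(side) if side.exists() else {}

    if path.suffix.lower() in (".edf", ".bdf"):
        labels, data, fs = _read_edf(path)
    else:
        df = pd.read_csv(path, sep="\t")
        labels = list(df.columns)
        data = df.to_numpy(dtype=float).T
        fs = float(meta["fs_hz"])

    by_label = dict(zip(labels, data))
    rows = sorted({int(lab[1 : lab.index("C")]) for lab in labels if lab.startswith("R") and "C" in lab})
    cols = sorted({int(lab[lab.index("C") + 1 :]) for lab in labels if lab.startswith("R") and "C" in lab})
    grid = np.stack(
        [np.stack([by_label[f"R{r}C{c}"] for c in cols]) for r in rows]
    )
    bipolar = by_label.get("BIP", np.zeros(grid.shape[2]))

    gt = meta.get("ground_truth")
    return GridRecording(
        grid_signals=grid,
        bipolar_signal=bipolar,
        fs_hz=float(meta.get("fs_hz", fs)),
        electrode_spacing_cm=float(meta.get("electrode_spacing_cm", 0.5)),
        toco_marks=[tuple(m) for m in meta.get("toco", [])],
        perception_marks=list(meta.get("perception", [])),
        ground_truth=_scenario_from_dict(gt) if gt else None,
    )


def _read_edf(path: Path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF/BDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.ch_names, raw.get_data() * 1e6, float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# result tables


def write_contractions_csv(segments: list[ContractionSegment], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset_s": [s.onset_s for s in segments],
            "duration_s": [s.duration_s for s in segments],
            "peak_psi": [s.peak_psi for s in segments],
            "confirmed_by": ["|".join(sorted(s.confirmed_by)) for s in segments],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_contractions_csv(path: str | Path) -> list[ContractionSegment]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        ContractionSegment(
            onset_s=float(r.onset_s),
            duration_s=float(r.duration_s),
            peak_psi=float(r.peak_psi),
            confirmed_by=frozenset(str(r.confirmed_by).split("|")) - {""},
        )
        for r in df.itertuples()
    ]


def write_cv_windows_csv(
    rows: list[tuple[str, float, DelayPair, CVVector]], path: str | Path
) -> Path:
    """One row per analysis window: identifiers, delays, CV, diagnostics."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "contraction_id": [cid for cid, *_ in rows],
            "start_s": [t for _, t, *_ in rows],
            "tau_r_s": [d.tau_r_s for *_, d, _ in rows],
            "tau_c_s": [d.tau_c_s for *_, d, _ in rows],
            "cv_cm_s": [v.amplitude_cm_s for *_, v in rows],
            "angle_rad": [v.angle_rad for *_, v in rows],
            "cost": [d.cost for *_, d, _ in rows],
            "converged": [d.converged for *_, d, _ in rows],
            "excluded": [v.excluded for *_, v in rows],
            "reason": [v.reason for *_, v in rows],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cv_windows_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def read_patients_csv(path: str | Path) -> pd.DataFrame:
    """Patient table with columns patient_id, hours_to_delivery."""
    df = pd.read_csv(path)
    missing = {"patient_id", "hours_to_delivery"} - set(df.columns)
    if missing:
        raise ValueError(f"patients table missing columns: {sorted(missing)}")
    return df
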