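"""Reading, writing and session-merging of multi-channel EMG recordings.

On disk a recording is a comma-separated file with a time column and one
column per muscle (values in μV), plus a small JSON sidecar
(``<file>.meta.json``) holding subject, session, movement, sampling rate
and the muscle → layer map. Directory layout: ``subject/session/movement.csv``.

Merging concatenates a subject's sessions per movement while recording
segment boundaries, so downstream RMS windows never span two sessions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import MUSCLES, EMGRecording

__all__ = [
    "RecordingFileSchema",
    "write_recording",
    "read_recording",
    "merge_sessions",
    "write_cohort",
    "read_cohort",
    "recording_path",
    "movement_slug",
]


@dataclass(frozen=True)
class RecordingFileSchema:
    """Column layout of a recording file: time column then muscle channels."""

    time_column: str = "time"
    channel_columns: tuple[str, ...] = MUSCLES
    units: str = "uV"

    def __post_init__(self) -> None:
        if not self.channel_columns:
            raise ValueError("schema needs at least one channel column")


DEFAULT_SCHEMA = RecordingFileSchema()


def movement_slug(movement: str) -> str:
    """Filesystem-safe name for a movement ("external rotation at 90° abduction"
    → "external_rotation_at_90_abduction")."""
    slug = re.sub(r"[^0-9a-zA-Z]+", "_", movement).strip("_").lower()
    return slug


def recording_path(root: Path | str, rec: EMGRecording) -> Path:
    return Path(root) / rec.subject_id / rec.session_id / f"{movement_slug(rec.movement)}.csv"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording(rec: EMGRecording, path: Path | str) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar.

    The CSV round-trips float64 values exactly (repr formatting); the
    sidecar carries everything needed to reconstruct the recording.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = rec.n_samples
    frame = pd.DataFrame({"time": np.arange(n) / rec.sampling_rate})
    for muscle, sig in rec.channels.items():
        frame[muscle] = np.asarray(sig, dtype=float)
    frame.to_csv(path, index=False, float_format="%.17g")  # exact float64 round-trip
    meta = {
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "movement": rec.movement,
        "sampling_rate": rec.sampling_rate,
        "layer_map": rec.layer_map,
        "segments": list(rec.segments),
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, ensure_ascii=False))


def read_recording(
    path: Path | str, schema: RecordingFileSchema | None = None
) -> EMGRecording:
    """Read a recording written by :func:`write_recording`.

    Validates the header against the schema; a missing channel column or a
    non-numeric cell is reported with its name / row index. The sampling
    rate must be present in the sidecar — it is never guessed.
    """
    path = Path(path)
    schema = schema or DEFAULT_SCHEMA
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate" not in meta or meta["sampling_rate"] is None:
        raise ValueError(f"sampling_rate absent from sidecar {sidecar}; refusing to guess")

    frame = pd.read_csv(path, float_precision="round_trip")
    for col in schema.channel_columns:
        if col not in frame.columns:
            raise ValueError(f"missing channel column {col!r} in {path}")
    channels: dict[str, np.ndarray] = {}
    for col in schema.channel_columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.index[values.isna() & frame[col].notna()]
        if len(bad) or values.isna().any():
            row = int(bad[0]) if len(bad) else int(values.index[values.isna()][0])
            raise ValueError(f"non-numeric cell in column {col!r} at row {row} of {path}")
        channels[col] = values.to_numpy(dtype=float)

    segments = tuple(meta.get("segments") or ())
    return EMGRecording(
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        movement=meta["movement"],
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
        layer_map=dict(meta.get("layer_map", {})),
        segments=segments,
    )


def write_cohort(recordings: Iterable[EMGRecording], root: Path | str) -> list[Path]:
    """Write a whole cohort under ``root`` in subject/session/movement layout."""
    paths = []
    for rec in recordings:
        p = recording_path(root, rec)
        write_recording(rec, p)
        paths.append(p)
    return paths


def read_cohort(root: Path | str, schema: RecordingFileSchema | None = None) -> list[EMGRecording]:
    """Read every recording below ``root`` (sorted for determinism)."""
    root = Path(root)
    paths = sorted(root.glob("*/*/*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recordings found under {root}")
    return [read_recording(p, schema) for p in paths]


def merge_sessions(recordings: list[EMGRecording]) -> dict[str, EMGRecording]:
    """Concatenate one subject's sessions per movement.

    Returns movement → merged recording whose ``segments`` record the
    per-session lengths, so windowing can avoid straddling the boundary.
    All inputs must share subject and sampling rate.
    """
    if not recordings:
        raise ValueError("no recordings to merge")
    subjects = {r.subject_id for r in recordings}
    if len(subjects) != 1:
        raise ValueError(f"cannot merge recordings from different subjects: {sorted(subjects)}")
    rates = {r.sampling_rate for r in recordings}
    if len(rates) != 1:
        raise ValueError(f"cannot merge recordings with mixed sampling rates: {sorted(rates)}")

    merged: dict[str, EMGRecording] = {}
    movements = []
    for rec in recordings:
        if rec.movement not in movements:
            movements.append(rec.movement)
    for movement in movements:
        parts = sorted(
            (r for r in recordings if r.movement == movement),
            key=lambda r: r.session_id,
        )
        muscles = parts[0].muscles
        channels = {
            m: np.concatenate([p.channels[m] for p in parts]) for m in muscles
        }
        segments = tuple(seg for p in parts for seg in p.segments)
        merged[movement] = EMGRecording(
            subject_id=parts[0].subject_id,
            session_id="+".join(p.session_id for p in parts),
            movement=movement,
            sampling_rate=parts[0].sampling_rate,
            channels=channels,
            layer_map=dict(parts[0].layer_map),
            segments=segments,
        )
    return merged
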