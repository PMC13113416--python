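"""Windowed RMS feature extraction, peak normalization, movement encoding.

Raw μV channels become the model's feature space in three steps: sliding
root-mean-square over 250-sample windows (125 ms at 2000 Hz), per
(subject, muscle) peak normalization to [0, 1] across both sessions and
all movements, and integer label encoding of the movement name. Windows
never straddle a session boundary of a merged recording.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import MOVEMENTS, MUSCLES, LAYER_MAP, EMGRecording

__all__ = [
    "MOVEMENT_CODES",
    "sliding_rms",
    "peak_normalize",
    "encode_movement",
    "decode_movement",
    "build_feature_table",
    "window_count",
]

ID_COLUMNS = ("subject_id", "session_id", "movement", "movement_code", "window_index")

# Fixed label encoding in canonical movement order; stable across runs.
MOVEMENT_CODES: dict[str, int] = {name: i for i, name in enumerate(MOVEMENTS)}


def encode_movement(name: str) -> int:
    """Fixed integer code for a movement name (scaption → 0, ...)."""
    try:
        return MOVEMENT_CODES[name]
    except KeyError:
        raise ValueError(
            f"unknown movement {name!r}; valid names: {list(MOVEMENT_CODES)}"
        ) from None


def decode_movement(code: int) -> str:
    for name, c in MOVEMENT_CODES.items():
        if c == code:
            return name
    raise ValueError(f"unknown movement code {code}; valid codes: 0..{len(MOVEMENTS) - 1}")


def window_count(n_samples: int, window_len: int, stride: int) -> int:
    """Number of full windows: floor((n − window) / stride) + 1, or 0."""
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // stride + 1


def sliding_rms(
    signal: np.ndarray | Sequence[float],
    window_len: int = 250,
    stride: int | None = None,
) -> np.ndarray:
    """Root mean square over sliding windows.

    The k-th output is the RMS of samples [k·stride, k·stride + window_len).
    ``stride`` defaults to ``window_len`` (non-overlapping windows). A
    signal shorter than one window is an error, never a silent truncation.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    stride = window_len if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(x) < window_len:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {window_len}-sample window"
        )
    n_windows = window_count(len(x), window_len, stride)
    # cumulative sum of squares: window mean-square in O(n)
    csum = np.concatenate(([0.0], np.cumsum(x**2)))
    starts = np.arange(n_windows) * stride
    sq_means = (csum[starts + window_len] - csum[starts]) / window_len
    return np.sqrt(np.maximum(sq_means, 0.0))


def _segmented_rms(
    signal: np.ndarray, segments: Sequence[int], window_len: int, stride: int
) -> np.ndarray:
    """Sliding RMS computed per segment so no window crosses a boundary."""
    parts = []
    offset = 0
    for seg_len in segments:
        seg = signal[offset : offset + seg_len]
        if len(seg) >= window_len:
            parts.append(sliding_rms(seg, window_len, stride))
        offset += seg_len
    if not parts:
        raise ValueError("every segment is shorter than one window")
    return np.concatenate(parts)


def peak_normalize(
    table: pd.DataFrame,
    muscles: Sequence[str] = MUSCLES,
    scope: str = "subject",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each muscle column by its per-group maximum.

    ``scope="subject"`` (default) normalizes per subject × muscle across
    both sessions and all movements, so each subject attains 1.0 at least
    once per muscle; ``scope="subject-session"`` normalizes within each
    session instead. Returns the normalized table and the recorded peaks
    (one row per group, one column per muscle) for the inverse transform.

    A group whose maximum is not strictly positive is a degenerate channel
    and raises, never divides by zero.
    """
    if scope == "subject":
        keys = ["subject_id"]
    elif scope == "subject-session":
        keys = ["subject_id", "session_id"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = table.copy()
    peaks = table.groupby(keys, sort=True)[list(muscles)].max()
    for group, row in peaks.iterrows():
        for muscle in muscles:
            if not row[muscle] > 0:
                raise ValueError(
                    f"all-zero/degenerate RMS for muscle {muscle!r} in group {group!r}"
                )
    for muscle in muscles:
        group_max = table.groupby(keys, sort=False)[muscle].transform("max")
        out[muscle] = table[muscle] / group_max
    return out, peaks


def build_feature_table(
    recordings: Iterable[EMGRecording],
    window_len: int = 250,
    stride: int | None = None,
    normalize: bool = True,
    scope: str = "subject",
) -> pd.DataFrame:
    """Windowed, peak-normalized RMS table for a cohort.

    One row per window per recording with identifier columns
    (subject, session, movement + its integer code, window index) and one
    normalized-RMS column per muscle. Windows respect session-boundary
    segments of merged recordings. Row count equals the sum over
    recordings of each recording's window count.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings supplied")
    stride = window_len if stride is None else stride
    muscle_set = recordings[0].muscles
    rows = []
    for rec in recordings:
        if rec.muscles != muscle_set:
            raise ValueError(
                f"inconsistent muscle set in recording {rec.subject_id}/{rec.session_id}"
                f"/{rec.movement}"
            )
        rms = {
            m: _segmented_rms(rec.channels[m], rec.segments, window_len, stride)
            for m in muscle_set
        }
        n_win = len(next(iter(rms.values())))
        block = pd.DataFrame(
            {
                "subject_id": rec.subject_id,
                "session_id": rec.session_id,
                "movement": rec.movement,
                "movement_code": encode_movement(rec.movement),
                "window_index": np.arange(n_win),
                **rms,
            }
        )
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)
    if normalize:
        table, peaks = peak_normalize(table, muscle_set, scope=scope)
        table.attrs["peaks"] = peaks
    table.attrs["muscles"] = muscle_set
    table.attrs["layer_map"] = dict(recordings[0].layer_map) or dict(LAYER_MAP)
    return table
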