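"""Readers and writers for signals, frames, annotations and feature tables.

All on-disk formats are plain text or PNG: EOG as CSV (``time_s`` plus the
four canonical monopolar channels, microvolts), frame sequences as
zero-padded indexed PNG files, event annotations as JSON lines, labels and
feature matrices as CSV.  EDF signal input is supported when :mod:`mne` is
installed.  Validation is strict: malformed inputs raise
:class:`~oculemo.errors.FormatError` rather than propagating silently.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import CANONICAL_CHANNELS, EventAnnotation, FrameSequence, MultiChannelEOG

_FRAME_RE = re.compile(r"(\d+)\.(png|tif|tiff|bmp|jpg|jpeg)$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# EOG signals
# ---------------------------------------------------------------------------

def write_eog(eog: MultiChannelEOG, path: str | Path) -> None:
    """Write an EOG trace as CSV with a ``time_s`` column."""
    df = pd.DataFrame(eog.data, columns=list(eog.channel_names))
    df.insert(0, "time_s", np.arange(eog.n_samples) / eog.fs)
    df.to_csv(path, index=False, float_format="%.12g")


def read_eog(path: str | Path, format: str = "csv") -> MultiChannelEOG:
    """Read an EOG recording, returning channels in canonical order.

    ``format`` is ``"csv"`` (a ``time_s`` column plus the four monopolar
    channels, any column order) or ``"edf"``.  The sampling rate is inferred
    from the time column (CSV) or the file header (EDF); non-uniform
    sampling, missing channels and NaNs are rejected.
    """
    if format == "csv":
        return _read_eog_csv(path)
    if format == "edf":
        return _read_eog_edf(path)
    raise ValidationError(f"unknown EOG format {format!r}; expected 'csv' or 'edf'")


def _read_eog_csv(path: str | Path) -> MultiChannelEOG:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required 'time_s' column")
    missing = [c for c in CANONICAL_CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")
    tt = df["time_s"].to_numpy(dtype=float)
    if len(tt) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(tt)
    if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean() + 1e-12:
        raise FormatError(f"{path}: non-uniform sampling in 'time_s'")
    data = df[list(CANONICAL_CHANNELS)].to_numpy(dtype=float)
    if np.isnan(data).any():
        raise FormatError(f"{path}: NaN values in channel data")
    return MultiChannelEOG(data, fs=1.0 / dt.mean())


def _read_eog_edf(path: str | Path) -> MultiChannelEOG:
    try:
        import mne
    except ImportError:
        raise FormatError(
            "EDF input requires the optional dependency 'mne' "
            "(pip install oculemo[edf])"
        ) from None
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    missing = [c for c in CANONICAL_CHANNELS if c not in raw.ch_names]
    if missing:
        raise FormatError(f"{path}: missing EDF channel(s) {missing}")
    picks = [raw.ch_names.index(c) for c in CANONICAL_CHANNELS]
    data = raw.get_data()[picks].T * 1e6  # mne stores volts; we use microvolts
    if np.isnan(data).any():
        raise FormatError(f"{path}: NaN values in channel data")
    return MultiChannelEOG(data, fs=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# Frame sequences
# ---------------------------------------------------------------------------

def write_frames(seq: FrameSequence, dir_path: str | Path) -> None:
    """Write frames as ``frame_000000.png`` ... under ``dir_path``."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(dir_path / f"frame_{i:06d}.png", frame)


def read_frames(dir_path: str | Path, fps: float = 30.0) -> FrameSequence:
    """Read an indexed image directory, sorted by numeric index.

    RGB inputs are kept as-is (color flag on the sequence) for later
    grayscale conversion; all frames must share one shape.
    """
    dir_path = Path(dir_path)
    entries = []
    for p in dir_path.iterdir() if dir_path.is_dir() else []:
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise FormatError(f"{dir_path}: no indexed image files found")
    entries.sort(key=lambda e: e[0])
    frames = [np.asarray(iio.imread(p)) for _, p in entries]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"{dir_path}: inconsistent frame shapes {sorted(shapes)}")
    return FrameSequence(np.stack(frames).astype(np.uint8), fps=fps)


# ---------------------------------------------------------------------------
# Event annotations (JSON lines)
# ---------------------------------------------------------------------------

def write_annotations(events: list[EventAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {"type": e.type.value, "start_s": e.start_s, "end_s": e.end_s}
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read JSON-lines annotations, returned sorted by start time."""
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                events.append(
                    EventAnnotation(rec["type"], rec["start_s"], rec["end_s"])
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed record: {exc}") from exc
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sorted(events, key=lambda e: e.start_s)


# ---------------------------------------------------------------------------
# Labels, pupil truth, features
# ---------------------------------------------------------------------------

def write_labels(rows: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["trial_id", "label"]).to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["trial_id", "label"]:
        raise FormatError(f"{path}: expected columns trial_id,label")
    return df


def write_pupil_truth(pupil_truth: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        pupil_truth, columns=["center_x", "center_y", "radius"]
    ).to_csv(path, index=False, float_format="%.12g")


def read_pupil_truth(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    expected = ["center_x", "center_y", "radius"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    return df.to_numpy(dtype=float)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-trial feature table (one row per trial, label last)."""
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: feature table must have a 'label' column")
    return df
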