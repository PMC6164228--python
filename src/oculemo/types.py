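"""Core in-memory containers shared across the pipeline.

Conventions used everywhere in this package:

* image coordinates: ``x`` is the column index, ``y`` the row index, both
  0-based;
* times are in seconds, sample/frame indices 0-based;
* event intervals are half-open ``[start_s, end_s)``;
* EOG amplitudes are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ValidationError

#: Canonical monopolar EOG channel order: horizontal right/left, vertical up/down.
CANONICAL_CHANNELS = ("HEOR", "HEOL", "VEOU", "VEOD")


class EventType(str, Enum):
    SACCADE = "saccade"
    FIXATION = "fixation"
    BLINK = "blink"


class Emotion(str, Enum):
    POSITIVE = "positive"
    NEUTRAL = "neutral"
    NEGATIVE = "negative"

    @classmethod
    def coerce(cls, value: "Emotion | str") -> "Emotion":
        try:
            return cls(value)
        except ValueError:
            raise ValidationError(
                f"unknown emotion label {value!r}; expected one of "
                f"{[e.value for e in cls]}"
            ) from None


EMOTIONS = (Emotion.POSITIVE, Emotion.NEUTRAL, Emotion.NEGATIVE)


@dataclass
class MultiChannelEOG:
    """Raw or filtered multi-channel EOG trace.

    Parameters
    ----------
    data : (n_samples, n_channels) float array, microvolts.
    fs : sampling rate in Hz.
    channel_names : one label per column.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValidationError("EOG data must be a 2-D samples x channels array")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.data.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{self.data.shape[1]} columns but {len(self.channel_names)} names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("EOG data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ValidationError(
                f"channel {name!r} not present (have {self.channel_names})"
            ) from None
        return self.data[:, idx]


@dataclass
class BipolarEOG:
    """Bipolar horizontal (HEOR−HEOL) and vertical (VEOU−VEOD) derivations."""

    horizontal: np.ndarray
    vertical: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        if self.horizontal.shape != self.vertical.shape:
            raise ValidationError("horizontal/vertical traces differ in length")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if not (
            np.all(np.isfinite(self.horizontal)) and np.all(np.isfinite(self.vertical))
        ):
            raise ValidationError("bipolar traces contain non-finite values")


@dataclass
class FrameSequence:
    """Timed sequence of video frames, 8-bit, grayscale or RGB."""

    frames: np.ndarray  # (n, h, w) gray or (n, h, w, 3) color, uint8
    fps: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.dtype != np.uint8:
            raise ValidationError("frames must be 8-bit (uint8)")
        if self.frames.ndim not in (3, 4) or (
            self.frames.ndim == 4 and self.frames.shape[-1] != 3
        ):
            raise ValidationError("frames must be (n,h,w) grayscale or (n,h,w,3) RGB")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValidationError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A typed oculomotor event over the half-open interval [start_s, end_s)."""

    start_s: float
    end_s: float
    type: EventType = field(compare=False)

    def __init__(self, type: EventType | str, start_s: float, end_s: float) -> None:
        object.__setattr__(self, "type", EventType(type))
        object.__setattr__(self, "start_s", float(start_s))
        object.__setattr__(self, "end_s", float(end_s))
        if not 0 <= self.start_s < self.end_s:
            raise ValidationError(
                f"need 0 <= start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
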