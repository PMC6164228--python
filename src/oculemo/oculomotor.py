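"""Oculomotor event detection and time-domain feature assembly.

Saccades are detected on the horizontal bipolar EOG trace with a Haar
continuous wavelet transform: the Haar wavelet responds maximally to the
step-like potential change of a saccade, the coefficient series is
thresholded at a fraction (default 1/3) of its own maximum magnitude, and
the resulting rectangular pulses are read as events (rising edge = start,
falling edge = end).  Detections outside the physiological 10-100 ms saccade
band are discarded.

Pupil size and position come from the eye video: each frame is converted to
grayscale, binarized with a threshold driven by the minimum pixel value
(the pupil is the darkest structure), and the pupil circle is recovered with
a circle Hough transform over the binary image's edge pixels.  Fixations are
detected from the per-frame pupil centers with a two-pass dispersion/duration
rule.  The module ends in the 11 time-domain features: max/mean/SD of
saccade duration + saccade frequency, the same four for fixations, and
max/mean/SD of pupil diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import EventAnnotation, EventType

DEFAULT_SCALE = 20
DEFAULT_THRESHOLD_FRAC = 1.0 / 3.0
SACCADE_DURATION_S = (0.010, 0.100)
FIXATION_DURATION_S = (0.100, 0.200)
FIXATION_STEP_PX = 1.0
FIXATION_DISPERSION_PX = 3.0
HOUGH_MIN_VOTES = 3
_EPS = 1e-12

#: Grayscale conversion weights (ITU-R 601 luma).
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Order of the 11 time-domain feature values.
FEATURE_NAMES = (
    "sac_max_dur",
    "sac_mean_dur",
    "sac_sd_dur",
    "sac_freq",
    "fix_max_dur",
    "fix_mean_dur",
    "fix_sd_dur",
    "fix_freq",
    "pupil_max_diam",
    "pupil_mean_diam",
    "pupil_sd_diam",
)


@dataclass
class PupilMeasurement:
    """Pupil circle estimate for one frame (x = column, y = row, in px)."""

    center_x: float
    center_y: float
    radius: float
    found: bool = True

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class TimeDomainFeatures:
    """The 11 scalar time-domain features (durations s, diameters px)."""

    sac_max_dur: float
    sac_mean_dur: float
    sac_sd_dur: float
    sac_freq: float
    fix_max_dur: float
    fix_mean_dur: float
    fix_sd_dur: float
    fix_freq: float
    pupil_max_diam: float
    pupil_mean_diam: float
    pupil_sd_diam: float

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# Saccades (EOG, Haar CWT)
# ---------------------------------------------------------------------------

def cwt_haar(trace: np.ndarray, fs: float, scale: int = DEFAULT_SCALE) -> np.ndarray:
    """Haar wavelet coefficients at one fixed scale, every integer shift.

    ``C[b] = (1/sqrt(a)) * sum_t x(b+t) * psi(t/a)`` with the Haar wavelet
    (+1 on the first half of its support, −1 on the second).  Positions where
    the wavelet support would overrun the trace are zero-padded, so the
    output has the input's length.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValidationError("trace must be 1-D")
    if scale < 2:
        raise ValidationError(f"scale must be >= 2, got {scale}")
    if len(trace) <= scale:
        raise ValidationError(
            f"trace of {len(trace)} samples is shorter than scale {scale}"
        )
    kernel = np.where(np.arange(scale) < scale / 2, 1.0, -1.0)
    coeff = np.zeros(len(trace))
    coeff[: len(trace) - scale + 1] = np.correlate(trace, kernel, mode="valid")
    coeff /= np.sqrt(scale)
    return coeff


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal True runs."""
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_saccades(
    horizontal: np.ndarray,
    fs: float,
    scale: int = DEFAULT_SCALE,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> list[EventAnnotation]:
    """Detect saccades on the horizontal bipolar trace.

    The wavelet magnitude is thresholded at ``threshold_frac`` of its own
    maximum; maximal supra-threshold runs become candidate events, and only
    candidates with durations inside the 10-100 ms saccade band survive.
    A flat trace (all-zero coefficients) yields an empty list.
    """
    if not 0 < threshold_frac < 1:
        raise ValidationError(
            f"threshold_frac must be in (0,1), got {threshold_frac}"
        )
    coeff = np.abs(cwt_haar(horizontal, fs, scale))
    peak = coeff.max()
    if peak == 0:
        return []
    th = threshold_frac * peak
    lo, hi = SACCADE_DURATION_S
    events = []
    for start, stop in _runs(coeff >= th):
        dur = (stop - start) / fs
        if lo - _EPS <= dur <= hi + _EPS:
            events.append(EventAnnotation(EventType.SACCADE, start / fs, stop / fs))
    return events


# ---------------------------------------------------------------------------
# Pupil (video)
# ---------------------------------------------------------------------------

def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale conversion, rounded to 8-bit."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValidationError(f"expected an (h, w, 3) RGB frame, got {frame.shape}")
    r, g, b = GRAY_WEIGHTS
    gray = r * frame[..., 0] + g * frame[..., 1] + b * frame[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def binarization_threshold(gray: np.ndarray) -> int:
    """Pupil binarization threshold driven by the minimum pixel value (MPV).

    Returns 4*MPV when MPV <= 20, 3*MPV when 20 < MPV <= 30, and 75 above:
    the darker the pupil, the tighter the threshold hugs it.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValidationError("empty image")
    mpv = int(gray.min())
    if mpv <= 20:
        return 4 * mpv
    if mpv <= 30:
        return 3 * mpv
    return 75


def binarize(gray: np.ndarray, th: int) -> np.ndarray:
    """Pixels above ``th`` become 1 (white); the dark pupil maps to 0."""
    if not 0 <= th <= 255:
        raise ValidationError(f"threshold must be in [0, 255], got {th}")
    return (np.asarray(gray) > th).astype(np.uint8)


def _edge_pixels(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Black pixels with at least one white 4-neighbor; returns (x, y)."""
    black = binary == 0
    white = ~black
    h, w = binary.shape
    neighbor_white = np.zeros_like(black)
    neighbor_white[1:, :] |= white[:-1, :]
    neighbor_white[:-1, :] |= white[1:, :]
    neighbor_white[:, 1:] |= white[:, :-1]
    neighbor_white[:, :-1] |= white[:, 1:]
    ys, xs = np.nonzero(black & neighbor_white)
    return xs, ys


_THETA = np.deg2rad(np.arange(360))
_COS = np.cos(_THETA)
_SIN = np.sin(_THETA)


def hough_circle(
    binary: np.ndarray, r_min: int, r_max: int
) -> PupilMeasurement:
    """Estimate the pupil circle from a binary image by Hough voting.

    Every edge pixel votes, for each candidate radius and each 1-degree
    angle, for the circle center it implies; the accumulator cell with the
    most votes wins.  Ties are broken toward the smallest radius, then the
    smallest (row, column) center.  ``found`` is False when the best cell
    collects fewer than 3 votes (no credible circle).
    """
    if r_min < 1 or r_max <= r_min:
        raise ValidationError(f"need 1 <= r_min < r_max, got [{r_min}, {r_max}]")
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ValidationError("binary image must be 2-D")
    h, w = binary.shape
    xs, ys = _edge_pixels(binary)
    best_votes, best = 0, (0.0, 0.0, 0.0)
    if len(xs) == 0:
        return PupilMeasurement(0.0, 0.0, 0.0, found=False)
    for r in range(r_min, r_max + 1):
        a = np.rint(xs[:, None] - r * _COS[None, :]).astype(np.int64)
        b = np.rint(ys[:, None] - r * _SIN[None, :]).astype(np.int64)
        valid = (a >= 0) & (a < w) & (b >= 0) & (b < h)
        idx = b[valid] * w + a[valid]
        if idx.size == 0:
            continue
        counts = np.bincount(idx, minlength=h * w)
        cell = int(np.argmax(counts))  # first max: smallest row, then column
        votes = int(counts[cell])
        if votes > best_votes:  # strict: earlier (smaller) radius wins ties
            best_votes = votes
            best = (float(cell % w), float(cell // w), float(r))
    if best_votes < HOUGH_MIN_VOTES:
        return PupilMeasurement(0.0, 0.0, 0.0, found=False)
    return PupilMeasurement(*best, found=True)


# ---------------------------------------------------------------------------
# Fixations (per-frame pupil centers)
# ---------------------------------------------------------------------------

def detect_fixations(
    centers: np.ndarray, fps: float
) -> list[EventAnnotation]:
    """Two-pass fixation detection on per-frame pupil centers.

    Pass 1 collects maximal runs of frames whose consecutive centers move at
    most 1 px on each axis.  Pass 2 keeps a run only if its duration
    (frames/fps) lies in [0.1, 0.2] s and its total dispersion (max − min)
    is at most 3 px on both axes.
    """
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2 or len(centers) < 2:
        raise ValidationError("need an (n >= 2, 2) array of (x, y) centers")
    steps = np.abs(np.diff(centers, axis=0))
    stable_pair = np.all(steps <= FIXATION_STEP_PX, axis=1)
    lo, hi = FIXATION_DURATION_S
    events = []
    for pstart, pstop in _runs(stable_pair):
        start, stop = pstart, pstop + 1  # pair run -> frame run
        dur = (stop - start) / fps
        if not (lo - _EPS <= dur <= hi + _EPS):
            continue
        span = centers[start:stop]
        disp = span.max(axis=0) - span.min(axis=0)
        if np.all(disp <= FIXATION_DISPERSION_PX):
            events.append(
                EventAnnotation(EventType.FIXATION, start / fps, stop / fps)
            )
    return events


# ---------------------------------------------------------------------------
# Time-domain feature assembly
# ---------------------------------------------------------------------------

def _duration_stats(events: list[EventAnnotation]) -> tuple[float, float, float]:
    if not events:
        return 0.0, 0.0, 0.0
    durs = np.array([e.duration_s for e in events])
    return float(durs.max()), float(durs.mean()), float(durs.std())


def time_domain_features(
    saccades: list[EventAnnotation],
    fixations: list[EventAnnotation],
    pupil: list[PupilMeasurement],
    segment_duration: float,
) -> TimeDomainFeatures:
    """Assemble the 11 time-domain features for one segment.

    Event frequencies are counts divided by ``segment_duration``; pupil
    statistics are taken over frames with a valid measurement (diameter =
    2 x radius).  Empty event lists yield zeros; if no frame has a valid
    pupil, the three pupil features are zero and a warning is emitted.
    """
    if segment_duration <= 0:
        raise ValidationError("segment_duration must be positive")
    sac_max, sac_mean, sac_sd = _duration_stats(saccades)
    fix_max, fix_mean, fix_sd = _duration_stats(fixations)
    diams = np.array([p.diameter for p in pupil if p.found])
    if diams.size:
        pup = (float(diams.max()), float(diams.mean()), float(diams.std()))
    else:
        warnings.warn("no valid pupil measurement in segment; pupil features = 0")
        pup = (0.0, 0.0, 0.0)
    return TimeDomainFeatures(
        sac_max, sac_mean, sac_sd, len(saccades) / segment_duration,
        fix_max, fix_mean, fix_sd, len(fixations) / segment_duration,
        *pup,
    )
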