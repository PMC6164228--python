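"""Class-conditional synthetic EOG trials and matching eye-video sequences.

No public recordings exist for the paired EOG + eye-video emotion task, so
this module synthesizes trials with exhaustive ground truth.  One latent
oculomotor "scan path" per trial — an alternating schedule of saccades
(step-like horizontal gaze shifts), fixations (gaze holds) and blinks
(vertical transients) — drives both the 4-channel EOG rendering and the
video rendering, so the two modalities of a trial are mutually consistent.

Emotion classes differ in their oculomotor statistics: a positive/excited
state shows faster and larger saccades with brief fixations and a dilated
pupil; a negative state shows sparse slow saccades, long fixations and a
moderately dilated pupil; neutral sits between on dynamics with the smallest
pupil (emotional arousal of either valence dilates the pupil).  All
magnitudes are free parameters of :class:`EmotionProfile`.

Everything is a pure function of (parameters, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .types import (
    EMOTIONS,
    Emotion,
    EventAnnotation,
    EventType,
    FrameSequence,
    MultiChannelEOG,
)

# Event-duration bounds (s) for the three oculomotor event types.
SACCADE_BOUNDS_S = (0.010, 0.100)
FIXATION_BOUNDS_S = (0.100, 0.200)
BLINK_BOUNDS_S = (0.100, 0.400)

#: Horizontal gaze excursion cap, in bipolar microvolts; keeps the rendered
#: pupil inside any reasonable frame once scaled.
GAZE_LIMIT_UV = 250.0
#: Per-frame inter-event gaze wander step (px) and its reflection limit.
WANDER_STEP_PX = 2
WANDER_LIMIT_PX = 10
#: Video rendering intensities (8-bit gray levels).
PUPIL_INTENSITY = 15
BACKGROUND_INTENSITY = 160
VIDEO_NOISE_SD = 2.0


@dataclass(frozen=True)
class EmotionProfile:
    """Generator parameters for one emotion class.

    Rates are events/s, durations seconds, amplitudes microvolts, pupil
    sizes pixels.
    """

    label: Emotion
    saccade_rate: float
    saccade_amplitude_mean: float
    saccade_duration_range: tuple[float, float]
    fixation_duration_range: tuple[float, float]
    blink_rate: float
    blink_duration_range: tuple[float, float]
    pupil_radius_mean: float
    pupil_radius_sd: float
    noise_sd: float
    drift_amplitude: float

    def __post_init__(self) -> None:
        if self.saccade_rate < 0 or self.blink_rate < 0:
            raise ValidationError("event rates must be nonnegative")
        for name, rng_, bounds in (
            ("saccade_duration_range", self.saccade_duration_range, SACCADE_BOUNDS_S),
            ("fixation_duration_range", self.fixation_duration_range, FIXATION_BOUNDS_S),
            ("blink_duration_range", self.blink_duration_range, BLINK_BOUNDS_S),
        ):
            lo, hi = rng_
            if not (bounds[0] <= lo <= hi <= bounds[1]):
                raise ValidationError(
                    f"{name}={rng_} must be ordered and inside {bounds}"
                )
        if self.pupil_radius_mean <= 0:
            raise ValidationError("pupil_radius_mean must be positive")
        if self.pupil_radius_sd < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValidationError("spreads/amplitudes must be nonnegative")


# Default class profiles.  Dynamics: positive = frequent fast large saccades
# and short fixations; negative = sparse slow saccades and long fixations;
# neutral intermediate.  Pupil: both emotional classes dilated vs neutral.
# Saccade-duration upper ends stay below ~65 ms so that the scale-20 Haar
# detector's supra-threshold run, roughly (2/3)(scale + rise) samples at
# 250 Hz, remains inside the 10-100 ms physiological gate.
_DEFAULTS: dict[Emotion, dict] = {
    Emotion.POSITIVE: dict(
        saccade_rate=2.2,
        saccade_amplitude_mean=110.0,
        saccade_duration_range=(0.020, 0.045),
        fixation_duration_range=(0.100, 0.140),
        blink_rate=0.40,
        blink_duration_range=(0.100, 0.300),
        pupil_radius_mean=22.0,
        pupil_radius_sd=1.2,
        noise_sd=5.0,
        drift_amplitude=20.0,
    ),
    Emotion.NEUTRAL: dict(
        saccade_rate=1.4,
        saccade_amplitude_mean=95.0,
        saccade_duration_range=(0.028, 0.055),
        fixation_duration_range=(0.125, 0.170),
        blink_rate=0.30,
        blink_duration_range=(0.100, 0.350),
        pupil_radius_mean=16.0,
        pupil_radius_sd=1.2,
        noise_sd=5.0,
        drift_amplitude=20.0,
    ),
    Emotion.NEGATIVE: dict(
        saccade_rate=0.7,
        saccade_amplitude_mean=80.0,
        saccade_duration_range=(0.035, 0.065),
        fixation_duration_range=(0.155, 0.200),
        blink_rate=0.25,
        blink_duration_range=(0.150, 0.400),
        pupil_radius_mean=20.0,
        pupil_radius_sd=1.2,
        noise_sd=5.0,
        drift_amplitude=20.0,
    ),
}


def make_emotion_profile(
    label: Emotion | str, overrides: dict | None = None
) -> EmotionProfile:
    """Return the default profile for ``label`` with ``overrides`` applied."""
    label = Emotion.coerce(label)
    params = dict(_DEFAULTS[label])
    valid = {f.name for f in dataclasses.fields(EmotionProfile)} - {"label"}
    for key, value in (overrides or {}).items():
        if key not in valid:
            raise ValidationError(
                f"unknown profile field {key!r}; valid fields: {sorted(valid)}"
            )
        params[key] = tuple(value) if key.endswith("_range") else value
    return EmotionProfile(label=label, **params)


@dataclass
class GroundTruth:
    """Exhaustive truth for a synthetic trial."""

    events: list[EventAnnotation]
    label: Emotion
    pupil_truth: np.ndarray | None = None  # (n_frames, 3): center_x, center_y, radius


# ---------------------------------------------------------------------------
# Latent scan path
# ---------------------------------------------------------------------------

@dataclass
class _Saccade:
    start: float
    duration: float
    amplitude: float  # per-monopolar step, uV; bipolar step is 2x
    sign: int


@dataclass
class _ScanPath:
    saccades: list[_Saccade]
    fixations: list[tuple[float, float]]  # (start, duration)
    blinks: list[tuple[float, float, float]]  # (start, duration, amplitude)
    pupil_base_radius: float
    pupil_mod_phase: float
    drift_freq: float
    drift_phases: np.ndarray  # one per EOG channel

    def events(self) -> list[EventAnnotation]:
        out = [
            EventAnnotation(EventType.SACCADE, s.start, s.start + s.duration)
            for s in self.saccades
        ]
        out += [
            EventAnnotation(EventType.FIXATION, t0, t0 + d)
            for t0, d in self.fixations
        ]
        out += [
            EventAnnotation(EventType.BLINK, t0, t0 + d)
            for t0, d, _ in self.blinks
        ]
        return sorted(out, key=lambda e: (e.start_s, e.type.value))


def _simulate_scanpath(
    profile: EmotionProfile, duration: float, seed: int
) -> _ScanPath:
    """Draw the latent trial schedule; independent of fs/fps so that EOG and
    video renderings of the same (profile, duration, seed) share it."""
    rng = np.random.default_rng([int(seed), 0])
    saccades: list[_Saccade] = []
    fixations: list[tuple[float, float]] = []
    lead = 0.3
    gaze = 0.0  # bipolar uV
    if profile.saccade_rate > 0:
        lo_s, hi_s = profile.saccade_duration_range
        lo_f, hi_f = profile.fixation_duration_range
        mean_cycle = 1.0 / profile.saccade_rate
        pause_mean = max(
            0.05, mean_cycle - (lo_s + hi_s) / 2 - (lo_f + hi_f) / 2 - 0.15
        )
        t = lead + rng.uniform(0, 0.2)
        while True:
            sac_dur = rng.uniform(lo_s, hi_s)
            fix_dur = rng.uniform(lo_f, hi_f)
            if t + sac_dur + fix_dur > duration - lead:
                break
            mean_a = profile.saccade_amplitude_mean
            amp = float(
                np.clip(rng.normal(mean_a, 0.08 * mean_a), 0.8 * mean_a, 1.2 * mean_a)
            )
            sign = 1 if rng.random() < 0.5 else -1
            if abs(gaze + sign * 2 * amp) > GAZE_LIMIT_UV:
                sign = -sign
            gaze += sign * 2 * amp
            saccades.append(_Saccade(t, sac_dur, amp, sign))
            t += sac_dur
            fixations.append((t, fix_dur))
            t += fix_dur
            t += 0.15 + rng.exponential(pause_mean)
    blinks: list[tuple[float, float, float]] = []
    if profile.blink_rate > 0:
        lo_b, hi_b = profile.blink_duration_range
        t = 0.5 + rng.exponential(1.0 / profile.blink_rate)
        while True:
            dur = rng.uniform(lo_b, hi_b)
            if t + dur > duration:
                break
            amp = 2.5 * profile.saccade_amplitude_mean * rng.uniform(0.8, 1.2)
            blinks.append((t, dur, amp))
            t += dur + 0.2 + rng.exponential(1.0 / profile.blink_rate)
    base_r = float(max(4.0, rng.normal(profile.pupil_radius_mean, profile.pupil_radius_sd)))
    return _ScanPath(
        saccades=saccades,
        fixations=fixations,
        blinks=blinks,
        pupil_base_radius=base_r,
        pupil_mod_phase=float(rng.uniform(0, 2 * np.pi)),
        drift_freq=float(rng.uniform(0.002, 0.005)),
        drift_phases=rng.uniform(0, 2 * np.pi, 4),
    )


def _raised_cosine_step(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """Smooth 0->1 step beginning at ``start`` and completing over ``duration``."""
    u = np.clip((t - start) / duration, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _horizontal_gaze(path: _ScanPath, t: np.ndarray) -> np.ndarray:
    """Clean per-monopolar horizontal component (uV); bipolar is twice this."""
    h = np.zeros_like(t)
    for s in path.saccades:
        h += s.sign * s.amplitude * _raised_cosine_step(t, s.start, s.duration)
    return h


def _blink_wave(path: _ScanPath, t: np.ndarray) -> np.ndarray:
    """Positive raised-cosine blink bumps (uV) on the vertical channels."""
    v = np.zeros_like(t)
    for start, dur, amp in path.blinks:
        u = (t - start) / dur
        inside = (u >= 0) & (u < 1)
        v[inside] += amp * 0.5 * (1.0 - np.cos(2 * np.pi * u[inside]))
    return v


# ---------------------------------------------------------------------------
# EOG rendering
# ---------------------------------------------------------------------------

def generate_eog_trial(
    profile: EmotionProfile, duration: float, fs: float, seed: int
) -> tuple[MultiChannelEOG, GroundTruth]:
    """Render the 4-channel EOG trace of a synthetic trial.

    Horizontal saccades appear as equal-magnitude, opposite-sign smoothed
    steps on HEOR/HEOL (so the bipolar step is twice the per-channel
    amplitude); blinks appear as transient spikes on VEOU/VEOD only.  White
    Gaussian noise and a slow (< 0.01 Hz) sinusoidal baseline drift are
    added per channel.
    """
    if duration <= 0 or fs <= 0:
        raise ValidationError("duration and fs must be positive")
    path = _simulate_scanpath(profile, duration, seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    h = _horizontal_gaze(path, t)
    blink = _blink_wave(path, t)
    channels = np.column_stack([h, -h, blink, -0.3 * blink])
    if profile.drift_amplitude > 0:
        drift = profile.drift_amplitude * np.sin(
            2 * np.pi * path.drift_freq * t[:, None] + path.drift_phases[None, :]
        )
        channels = channels + drift
    if profile.noise_sd > 0:
        noise_rng = np.random.default_rng([int(seed), 1])
        channels = channels + noise_rng.normal(0, profile.noise_sd, channels.shape)
    eog = MultiChannelEOG(channels, fs)
    return eog, GroundTruth(events=path.events(), label=profile.label)


# ---------------------------------------------------------------------------
# Video rendering
# ---------------------------------------------------------------------------

def generate_eye_video(
    profile: EmotionProfile,
    duration: float,
    fps: float,
    width: int,
    height: int,
    seed: int,
) -> tuple[FrameSequence, GroundTruth]:
    """Render grayscale eye frames with a dark pupil disk following the gaze.

    The disk center tracks the EOG-implied horizontal gaze, frozen during
    ground-truth fixations and augmented with a +/-2 px random wander
    between events so that stable runs coincide exactly with fixations.
    Per-frame center and radius are recorded in ``pupil_truth``.
    """
    if duration <= 0 or fps <= 0 or width <= 0 or height <= 0:
        raise ValidationError("duration, fps, width, height must be positive")
    r_reach = profile.pupil_radius_mean + 3 * profile.pupil_radius_sd
    if r_reach >= min(width, height) / 2:
        raise ValidationError(
            f"pupil (mean + 3 sd = {r_reach:.1f} px) does not fit in a "
            f"{width}x{height} frame"
        )
    path = _simulate_scanpath(profile, duration, seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    # horizontal position: gaze scaled so the full excursion stays in-frame
    margin = r_reach + WANDER_LIMIT_PX + 4
    px_per_uv = max(width / 2 - margin, 4.0) / GAZE_LIMIT_UV
    x_float = width / 2 + px_per_uv * 2 * _horizontal_gaze(path, t)

    in_fixation = np.zeros(n, dtype=bool)
    for t0, d in path.fixations:
        in_fixation |= (t >= t0 - 1e-9) & (t < t0 + d - 1e-9)

    # inter-event micro-wander breaks center stability outside fixations;
    # a trial with no scanning activity keeps a perfectly static gaze
    wander_rng = np.random.default_rng([int(seed), 3])
    wander = np.zeros(n)
    if path.saccades:
        w_pos, w_dir = 0.0, 1.0
        for i in range(1, n):
            if in_fixation[i] and in_fixation[i - 1]:
                pass  # gaze frozen within a fixation
            else:
                if wander_rng.random() < 0.2:
                    w_dir = -w_dir
                if abs(w_pos + w_dir * WANDER_STEP_PX) > WANDER_LIMIT_PX:
                    w_dir = -w_dir
                w_pos += w_dir * WANDER_STEP_PX
            wander[i] = w_pos

    cx = np.rint(np.clip(x_float + wander, r_reach + 2, width - r_reach - 3))
    cy = np.full(n, np.rint(height / 2.0))
    # slow hippus-like radius oscillation; part of the stochastic rendering,
    # so fully deterministic (noise-free) trials keep a constant radius
    radius = np.full(n, np.rint(path.pupil_base_radius))
    if profile.noise_sd > 0:
        radius = np.rint(
            path.pupil_base_radius
            + 0.75 * np.sin(2 * np.pi * 0.1 * t + path.pupil_mod_phase)
        )
    # a fixation's frames must share one center: re-freeze after clipping
    for t0, d in path.fixations:
        idx = np.flatnonzero((t >= t0 - 1e-9) & (t < t0 + d - 1e-9))
        if idx.size:
            cx[idx] = cx[idx[0]]
            radius[idx] = radius[idx[0]]

    noise_rng = np.random.default_rng([int(seed), 2])
    yy, xx = np.mgrid[0:height, 0:width]
    frames = np.empty((n, height, width), dtype=np.uint8)
    for i in range(n):
        img = np.full((height, width), float(BACKGROUND_INTENSITY))
        mask = (xx - cx[i]) ** 2 + (yy - cy[i]) ** 2 <= (radius[i] + 0.5) ** 2
        img[mask] = PUPIL_INTENSITY
        if profile.noise_sd > 0:
            img += noise_rng.normal(0, VIDEO_NOISE_SD, img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pupil_truth = np.column_stack([cx, cy, radius])
    seq = FrameSequence(frames, fps)
    return seq, GroundTruth(
        events=path.events(), label=profile.label, pupil_truth=pupil_truth
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Configuration of a balanced synthetic dataset."""

    trials_per_class: int = 10
    duration_s: float = 10.0
    fs: float = 250.0
    fps: float = 30.0
    width: int = 160
    height: int = 120
    include_video: bool = True
    profile_overrides: dict = field(default_factory=dict)  # label -> overrides

    def __post_init__(self) -> None:
        if self.trials_per_class < 1:
            raise ValidationError("trials_per_class must be >= 1")

    def profile(self, label: Emotion) -> EmotionProfile:
        return make_emotion_profile(label, self.profile_overrides.get(label.value))


def generate_dataset(config: DatasetConfig, out_dir: str | Path, seed: int) -> dict:
    """Write a balanced synthetic dataset and return its manifest.

    Layout: ``trial_<idx>/eog.csv``, ``trial_<idx>/events.jsonl``,
    ``trial_<idx>/pupil_truth.csv`` and ``trial_<idx>/frames/frame_*.png``
    (when video is included), plus ``labels.csv`` and ``manifest.json`` at
    the root.  Trial ``i`` uses seed ``seed + i``; classes cycle
    positive/neutral/negative so the dataset is balanced.
    """
    from . import io as oio  # deferred: io imports types only

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory {out_dir} is not writable: {exc}")
    trials = []
    labels_rows = []
    n_total = 3 * config.trials_per_class
    for i in range(n_total):
        label = EMOTIONS[i % 3]
        profile = config.profile(label)
        trial_seed = int(seed) + i
        trial_id = f"trial_{i:03d}"
        tdir = out_dir / trial_id
        tdir.mkdir(exist_ok=True)
        eog, truth = generate_eog_trial(profile, config.duration_s, config.fs, trial_seed)
        oio.write_eog(eog, tdir / "eog.csv")
        oio.write_annotations(truth.events, tdir / "events.jsonl")
        entry = {
            "trial_id": trial_id,
            "label": label.value,
            "seed": trial_seed,
            "eog": f"{trial_id}/eog.csv",
            "events": f"{trial_id}/events.jsonl",
        }
        if config.include_video:
            video, vtruth = generate_eye_video(
                profile, config.duration_s, config.fps,
                config.width, config.height, trial_seed,
            )
            oio.write_frames(video, tdir / "frames")
            oio.write_pupil_truth(vtruth.pupil_truth, tdir / "pupil_truth.csv")
            entry["frames"] = f"{trial_id}/frames"
            entry["pupil_truth"] = f"{trial_id}/pupil_truth.csv"
        trials.append(entry)
        labels_rows.append((trial_id, label.value))
    oio.write_labels(labels_rows, out_dir / "labels.csv")
    manifest = {
        "seed": int(seed),
        "config": {
            "trials_per_class": config.trials_per_class,
            "duration_s": config.duration_s,
            "fs": config.fs,
            "fps": config.fps,
            "width": config.width,
            "height": config.height,
            "include_video": config.include_video,
            "profile_overrides": config.profile_overrides,
        },
        "trials": trials,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
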