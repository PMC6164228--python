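"""End-to-end per-trial feature extraction and the synthetic benchmark.

``extract_trial_features`` turns one trial (4-channel EOG, optionally an eye
video) into the classifier inputs: the flattened STFT magnitude vector and
the 11 time-domain oculomotor features.  ``generate_benchmark_samples``
builds the package's default labelled benchmark fully in memory by running
that extraction over synthetic trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import oculomotor as om
from . import preprocess as pp
from . import tf_features as tf
from .errors import ValidationError
from .fusion import TrialSample
from .synth import DatasetConfig, generate_eog_trial, generate_eye_video
from .types import EMOTIONS, EventAnnotation, FrameSequence, MultiChannelEOG


def measure_pupil_series(
    seq: FrameSequence,
    r_min: int = 5,
    r_max: int | None = None,
    track: bool = True,
) -> list[om.PupilMeasurement]:
    """Per-frame pupil circle estimates for a frame sequence.

    Each frame is grayscaled (if RGB), binarized with the MPV-driven
    threshold and passed to the circle Hough transform.  With ``track``
    enabled, after the first confident detection the radius search narrows
    to +/-2 px around the previous estimate, which follows the slow pupil
    dynamics at a fraction of the full search cost; the spatial vote space
    is never restricted, so gaze jumps are not lost.
    """
    h, w = seq.frames.shape[1:3]
    if r_max is None:
        r_max = max(r_min + 1, min(h, w) // 4)
    out: list[om.PupilMeasurement] = []
    prev_r: float | None = None
    for frame in seq.frames:
        gray = om.rgb_to_gray(frame) if seq.is_color else frame
        th = om.binarization_threshold(gray)
        binary = om.binarize(gray, th)
        if track and prev_r is not None:
            lo = max(r_min, int(prev_r) - 2)
            hi = min(r_max, int(prev_r) + 2)
            m = om.hough_circle(binary, lo, max(hi, lo + 1))
        else:
            m = om.hough_circle(binary, r_min, r_max)
        if m.found:
            prev_r = m.radius
        out.append(m)
    return out


def pupil_centers(measurements: list[om.PupilMeasurement]) -> np.ndarray:
    """(n, 2) center series; frames without a detection are bridged with the
    most recent valid center (leading gaps take the first valid one)."""
    centers = np.full((len(measurements), 2), np.nan)
    for i, m in enumerate(measurements):
        if m.found:
            centers[i] = (m.center_x, m.center_y)
    valid = ~np.isnan(centers[:, 0])
    if not valid.any():
        return np.empty((0, 2))
    first = int(np.flatnonzero(valid)[0])
    centers[:first] = centers[first]
    for i in range(first + 1, len(centers)):
        if np.isnan(centers[i, 0]):
            centers[i] = centers[i - 1]
    return centers


def extract_trial_features(
    eog: MultiChannelEOG,
    video: FrameSequence | None = None,
    *,
    filter_order: int = pp.DEFAULT_ORDER,
    low_hz: float = pp.DEFAULT_LOW_HZ,
    high_hz: float = pp.DEFAULT_HIGH_HZ,
    window_s: float = tf.DEFAULT_WINDOW_S,
    hop_s: float = tf.DEFAULT_HOP_S,
    L: int = tf.DEFAULT_L,
    scale: int = om.DEFAULT_SCALE,
    threshold_frac: float = om.DEFAULT_THRESHOLD_FRAC,
    include_vertical_saccades: bool = False,
    r_min: int = 5,
    r_max: int | None = None,
) -> tuple[np.ndarray, om.TimeDomainFeatures, dict[str, list[EventAnnotation]]]:
    """Extract the TF vector and 11 time-domain features for one trial.

    Returns ``(tf_vector, td_features, events)`` where ``events`` maps
    ``"saccade"``/``"fixation"`` to the detected annotations.  Saccades are
    detected on the horizontal bipolar trace (optionally unioned with
    vertical-trace detections); fixations and pupil features require the
    video and are zero without it.
    """
    filtered = pp.bandpass_filter(eog, order=filter_order, low=low_hz, high=high_hz)
    bip = pp.derive_bipolar(filtered)
    spec_h = tf.stft(bip.horizontal, eog.fs, window_s, hop_s, L)
    spec_v = tf.stft(bip.vertical, eog.fs, window_s, hop_s, L)
    tf_vec = tf.tf_feature_vector([spec_h, spec_v])
    saccades = om.detect_saccades(bip.horizontal, eog.fs, scale, threshold_frac)
    if include_vertical_saccades:
        extra = om.detect_saccades(bip.vertical, eog.fs, scale, threshold_frac)
        saccades = sorted(saccades + extra, key=lambda e: e.start_s)
    fixations: list[EventAnnotation] = []
    pupil: list[om.PupilMeasurement] = []
    if video is not None:
        pupil = measure_pupil_series(video, r_min=r_min, r_max=r_max)
        centers = pupil_centers(pupil)
        if len(centers) >= 2:
            fixations = om.detect_fixations(centers, video.fps)
    td = om.time_domain_features(saccades, fixations, pupil, eog.duration_s)
    return tf_vec, td, {"saccade": saccades, "fixation": fixations}


def features_to_frame(samples: list[TrialSample]) -> pd.DataFrame:
    """One row per trial: tf_0000... columns, the 11 named time-domain
    features, then the label."""
    if not samples:
        raise ValidationError("no samples")
    n_tf = samples[0].tf.size
    cols = [f"tf_{i:04d}" for i in range(n_tf)] + list(om.FEATURE_NAMES)
    rows = [np.concatenate([s.tf, s.td]) for s in samples]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "trial_id", [s.trial_id for s in samples])
    df["label"] = [s.label.value for s in samples]
    return df


def frame_to_samples(df: pd.DataFrame) -> list[TrialSample]:
    tf_cols = [c for c in df.columns if c.startswith("tf_")]
    td_cols = list(om.FEATURE_NAMES)
    samples = []
    for _, row in df.iterrows():
        samples.append(
            TrialSample(
                tf=row[tf_cols].to_numpy(dtype=float),
                td=row[td_cols].to_numpy(dtype=float),
                label=row["label"],
                trial_id=str(row.get("trial_id", "")),
            )
        )
    return samples


def default_benchmark_config(trials_per_class: int = 60) -> DatasetConfig:
    """The package's default labelled benchmark: 10-s trials at 250 Hz EOG /
    30 fps video on 160x120 frames, default class profiles."""
    return DatasetConfig(
        trials_per_class=trials_per_class,
        duration_s=10.0,
        fs=250.0,
        fps=30.0,
        width=160,
        height=120,
    )


def generate_benchmark_samples(
    config: DatasetConfig | None = None,
    seed: int = 42,
    with_video: bool = True,
) -> list[TrialSample]:
    """Generate the benchmark and run full feature extraction in memory.

    Trial ``i`` (labels cycling positive/neutral/negative) uses seed
    ``seed + i`` for both modalities, so EOG and video share one latent
    scan path per trial.
    """
    config = config or default_benchmark_config()
    samples = []
    for i in range(3 * config.trials_per_class):
        label = EMOTIONS[i % 3]
        profile = config.profile(label)
        trial_seed = int(seed) + i
        eog, _ = generate_eog_trial(profile, config.duration_s, config.fs, trial_seed)
        video = None
        if with_video and config.include_video:
            video, _ = generate_eye_video(
                profile, config.duration_s, config.fps,
                config.width, config.height, trial_seed,
            )
        tf_vec, td, _ = extract_trial_features(eog, video)
        samples.append(
            TrialSample(tf=tf_vec, td=td, label=label, trial_id=f"trial_{i:03d}")
        )
    return samples
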