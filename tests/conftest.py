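import numpy as np
import pytest

import oculemo as oc


@pytest.fixture(scope="session")
def benchmark_samples():
    """The default synthetic benchmark: 60 trials per class, seed 42,
    full EOG + video feature extraction.  Shared across evaluation tests."""
    return oc.generate_benchmark_samples(seed=42)


@pytest.fixture()
def quiet_profile():
    """Noise- and drift-free neutral profile (deterministic waveforms)."""
    return oc.make_emotion_profile(
        "neutral", {"noise_sd": 0.0, "drift_amplitude": 0.0}
    )


@pytest.fixture()
def small_trial(quiet_profile):
    """A short noise-free trial with its ground truth."""
    return oc.generate_eog_trial(quiet_profile, duration=8.0, fs=250.0, seed=3)


def make_disk_image(h, w, cx, cy, r, background=1):
    """Binary image with a black disk (value 0) on a white background."""
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (r + 0.5) ** 2
    img = np.full((h, w), background, dtype=np.uint8)
    img[mask] = 0
    return img
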