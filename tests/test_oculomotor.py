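import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oculemo as oc
from oculemo.errors import ValidationError
from oculemo.oculomotor import FEATURE_NAMES

from conftest import make_disk_image


def cwt_haar_bruteforce(trace, scale):
    """Literal double-loop evaluation of the fixed-scale Haar transform."""
    n = len(trace)
    out = np.zeros(n)
    for b in range(n - scale + 1):
        acc = 0.0
        for t in range(scale):
            psi = 1.0 if (t / scale) < 0.5 else -1.0
            acc += trace[b + t] * psi
        out[b] = acc / np.sqrt(scale)
    return out


def fixation_oracle(centers, fps):
    """Literal nested-loop implementation of the two-pass fixation rule."""
    n = len(centers)
    events = []
    i = 0
    while i < n - 1:
        if abs(centers[i + 1][0] - centers[i][0]) <= 1 and abs(
            centers[i + 1][1] - centers[i][1]
        ) <= 1:
            j = i
            while j < n - 1 and abs(centers[j + 1][0] - centers[j][0]) <= 1 and abs(
                centers[j + 1][1] - centers[j][1]
            ) <= 1:
                j += 1
            run = centers[i : j + 1]
            dur = len(run) / fps
            xs = [c[0] for c in run]
            ys = [c[1] for c in run]
            if 0.1 <= dur <= 0.2 and max(xs) - min(xs) <= 3 and max(ys) - min(ys) <= 3:
                events.append((i / fps, (j + 1) / fps))
            i = j
        else:
            i += 1
    return events


class TestCwtHaar:
    def test_constant_trace_vanishes(self):
        assert np.allclose(oc.cwt_haar(np.full(200, 7.0), 250.0), 0.0)

    def test_step_response_peaks_at_step(self):
        x = np.zeros(300)
        x[100:] = 1.0
        c = oc.cwt_haar(x, 250.0, scale=20)
        # wavelet support [b, b+scale): |C| peaks when the step bisects it
        assert abs(int(np.argmax(np.abs(c))) - 90) <= 1
        brute = cwt_haar_bruteforce(x, 20)
        assert abs(brute[90]) == np.abs(brute).max()

    @pytest.mark.parametrize("scale", [4, 7, 20])
    def test_matches_bruteforce(self, scale):
        rng = np.random.default_rng(scale)
        x = rng.normal(size=200)
        assert np.allclose(
            oc.cwt_haar(x, 250.0, scale), cwt_haar_bruteforce(x, scale), atol=1e-9
        )

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            oc.cwt_haar(np.zeros(10), 250.0, scale=20)


class TestDetectSaccades:
    def test_flat_trace_gives_no_events(self):
        assert oc.detect_saccades(np.zeros(1000), 250.0) == []

    def test_single_step_detected_once(self):
        fs = 250.0
        t = np.arange(int(2 * fs)) / fs
        # 40 ms smoothed step at t = 1 s
        x = 100.0 * np.clip((t - 1.0) / 0.04, 0, 1)
        events = oc.detect_saccades(x, fs)
        assert len(events) == 1
        tol = 20 / fs
        assert abs(events[0].start_s - 1.0) <= tol
        assert abs(events[0].end_s - 1.04) <= tol

    def test_slow_ramp_removed_by_duration_gate(self):
        fs = 250.0
        t = np.arange(int(2 * fs)) / fs
        x = 100.0 * np.clip((t - 0.5) / 0.15, 0, 1)  # 150 ms ramp
        assert oc.detect_saccades(x, fs) == []

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            oc.detect_saccades(np.zeros(100), 250.0, threshold_frac=1.5)


class TestGrayscale:
    def test_black_stays_black(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        assert np.all(oc.rgb_to_gray(img) == 0)

    def test_uniform_gray_preserved(self):
        img = np.full((4, 4, 3), 100, dtype=np.uint8)
        assert np.all(oc.rgb_to_gray(img) == 100)

    def test_pure_red_weight(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert np.all(oc.rgb_to_gray(img) == 76)  # round(0.299 * 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValidationError):
            oc.rgb_to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestBinarization:
    @pytest.mark.parametrize(
        "mpv,expected",
        [(0, 0), (10, 40), (20, 80), (21, 63), (25, 75), (30, 90), (31, 75), (50, 75), (200, 75)],
    )
    def test_threshold_branches(self, mpv, expected):
        img = np.full((5, 5), 220, dtype=np.uint8)
        img[0, 0] = mpv
        assert oc.binarization_threshold(img) == expected

    def test_binarize_uniform_and_boundary(self):
        assert np.all(oc.binarize(np.full((3, 3), 200, np.uint8), 75) == 1)
        assert np.all(oc.binarize(np.full((3, 3), 200, np.uint8), 255) == 0)

    def test_pupil_region_maps_to_black(self):
        profile = oc.make_emotion_profile("neutral")
        video, truth = oc.generate_eye_video(profile, 0.5, 30, 160, 120, seed=2)
        frame = video.frames[0]
        th = oc.binarization_threshold(frame)
        binary = oc.binarize(frame, th)
        cx, cy, r = truth.pupil_truth[0]
        yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (r - 1) ** 2
        assert (binary[mask] == 0).mean() >= 0.95


class TestHoughCircle:
    def test_exact_recovery_on_clean_disks(self):
        for cx in (60, 100, 140):
            for cy in (40, 80, 120):
                for r in (10, 20, 30):
                    img = make_disk_image(200, 200, cx, cy, r)
                    m = oc.hough_circle(img, 5, 40)
                    assert m.found
                    assert (m.center_x, m.center_y, m.radius) == (cx, cy, r)

    def test_all_white_image_not_found(self):
        m = oc.hough_circle(np.ones((50, 50), dtype=np.uint8), 5, 20)
        assert not m.found

    def test_salt_noise_tolerance(self):
        rng = np.random.default_rng(0)
        img = make_disk_image(200, 200, 100, 80, 20)
        salt = rng.random(img.shape) < 0.01
        img = img.copy()
        img[salt] = 1 - img[salt]
        m = oc.hough_circle(img, 5, 40)
        assert m.found
        assert abs(m.center_x - 100) <= 1
        assert abs(m.center_y - 80) <= 1
        assert abs(m.radius - 20) <= 1

    def test_monotone_in_disk_radius(self):
        diams = []
        for r in (8, 12, 16, 20):
            img = make_disk_image(120, 120, 60, 60, r)
            diams.append(oc.hough_circle(img, 4, 30).diameter)
        assert all(b > a for a, b in zip(diams, diams[1:]))

    def test_bad_radius_range_rejected(self):
        with pytest.raises(ValidationError):
            oc.hough_circle(np.ones((10, 10), np.uint8), 5, 5)

    def test_agrees_with_skimage_on_clean_disk(self):
        # independent library route: skimage votes on the same edge map
        from skimage.transform import hough_circle as sk_hough

        img = make_disk_image(160, 160, 70, 90, 18)
        ours = oc.hough_circle(img, 10, 26)
        # same edge definition (black pixels bordering white) for both routes
        from oculemo.oculomotor import _edge_pixels

        xs, ys = _edge_pixels(img)
        edge_img = np.zeros_like(img, dtype=bool)
        edge_img[ys, xs] = True
        radii = np.arange(10, 27)
        acc = sk_hough(edge_img, radii)
        best = np.unravel_index(np.argmax(acc), acc.shape)
        sk_r, sk_cy, sk_cx = radii[best[0]], best[1], best[2]
        assert (ours.center_x, ours.center_y, ours.radius) == (sk_cx, sk_cy, sk_r)
        assert (sk_cx, sk_cy, sk_r) == (70, 90, 18)


class TestDetectFixations:
    def test_five_stable_frames_is_one_fixation(self):
        centers = np.tile([50.0, 40.0], (5, 1))
        centers = np.vstack([[30.0, 40.0], centers, [70.0, 40.0]])
        events = oc.detect_fixations(centers, 30.0)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(5 / 30)

    def test_ten_stable_frames_too_long(self):
        centers = np.tile([50.0, 40.0], (10, 1))
        assert oc.detect_fixations(centers, 30.0) == []

    def test_drifting_centers_rejected(self):
        centers = np.column_stack([np.arange(6) * 2.0, np.zeros(6)])
        assert oc.detect_fixations(centers, 30.0) == []

    def test_slow_creep_caught_by_dispersion(self):
        # 1 px/frame passes the pair rule but spans > 3 px over 5 frames
        centers = np.column_stack([np.arange(5) * 1.0, np.zeros(5)])
        assert oc.detect_fixations(centers, 30.0) == []

    def test_bad_fps_rejected(self):
        with pytest.raises(ValidationError):
            oc.detect_fixations(np.zeros((5, 2)), 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_literal_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.choice([-2, -1, 0, 1, 2], size=(40, 2), p=[0.1, 0.2, 0.4, 0.2, 0.1])
        centers = np.cumsum(steps, axis=0).astype(float)
        got = [
            (e.start_s, e.end_s) for e in oc.detect_fixations(centers, 30.0)
        ]
        expected = fixation_oracle([tuple(c) for c in centers], 30.0)
        assert got == pytest.approx(expected)


class TestTimeDomainFeatures:
    def test_feature_vector_has_11_values(self):
        pupil = [oc.PupilMeasurement(10, 10, 20.0)] * 5
        td = oc.time_domain_features([], [], pupil, 60.0)
        assert td.vector().shape == (11,)
        assert len(FEATURE_NAMES) == 11

    def test_degenerate_events_constant_pupil(self):
        pupil = [oc.PupilMeasurement(10, 10, 20.0)] * 5
        td = oc.time_domain_features([], [], pupil, 60.0)
        assert np.allclose(td.vector()[:8], 0.0)
        assert td.pupil_max_diam == 40.0
        assert td.pupil_mean_diam == 40.0
        assert td.pupil_sd_diam == 0.0

    def test_hand_computed_saccade_stats(self):
        sacs = [
            oc.EventAnnotation("saccade", 1.0, 1.02),
            oc.EventAnnotation("saccade", 2.0, 2.04),
        ]
        td = oc.time_domain_features(sacs, [], [], 60.0)
        assert td.sac_max_dur == pytest.approx(0.04)
        assert td.sac_mean_dur == pytest.approx(0.03)
        assert td.sac_freq == pytest.approx(2 / 60)

    def test_no_pupil_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="pupil"):
            td = oc.time_domain_features([], [], [], 10.0)
        assert td.pupil_mean_diam == 0.0
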