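"""The bespoke core: Prewitt edges, iris localization, and the ratio rule."""

import numpy as np
import pytest

from gazepref import (
    BrightnessProfile,
    EyeRenderSpec,
    GazeConfig,
    GazeLabel,
    NoIrisError,
    ScleraBrightness,
    black_region_enhance,
    brightness_profile,
    classify_eye,
    classify_frame,
    classify_gaze,
    detection_from_truth,
    iris_offset_for_label,
    locate_iris,
    prewitt_edges,
    render_eye,
    render_face,
    sclera_peaks,
)
from gazepref.gaze import DegenerateProfileError
from gazepref.types import IrisLocation, Region


class TestPrewitt:
    def test_constant_raster_zero_magnitude(self):
        np.testing.assert_array_equal(
            prewitt_edges(np.full((6, 7), 42.0)), np.zeros((6, 7))
        )

    def test_vertical_step_interior_magnitude_3h(self):
        h = 11.0
        raster = np.zeros((8, 10))
        raster[:, 5:] = h
        mag = prewitt_edges(raster)
        # Columns adjacent to the step see the full unnormalized response.
        np.testing.assert_allclose(mag[2:6, 4], 3 * h)
        np.testing.assert_allclose(mag[2:6, 5], 3 * h)
        np.testing.assert_allclose(mag[2:6, 2], 0.0)

    def test_matches_hand_convolution_oracle(self):
        # Independent oracle: direct nested-loop convolution on a padded copy.
        rng = np.random.default_rng(12)
        raster = rng.uniform(0, 255, (7, 9))
        padded = np.pad(raster, 1, mode="symmetric")  # edge-repeating reflection
        kx = np.array([[1, 0, -1]] * 3, dtype=float)
        expected = np.zeros_like(raster)
        for i in range(raster.shape[0]):
            for j in range(raster.shape[1]):
                win = padded[i : i + 3, j : j + 3]
                # correlate == convolve for these point-symmetric-up-to-sign
                # kernels only in magnitude; convolution flips the kernel.
                gx = (win * kx[::-1, ::-1]).sum()
                gy = (win * kx.T[::-1, ::-1]).sum()
                expected[i, j] = np.hypot(gx, gy)
        np.testing.assert_allclose(prewitt_edges(raster), expected)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        raster = rng.uniform(0, 255, (9, 12))
        np.testing.assert_allclose(
            prewitt_edges(raster[:, ::-1]), prewitt_edges(raster)[:, ::-1]
        )

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError):
            prewitt_edges(np.zeros((2, 5)))


def _dark_channel(spec: EyeRenderSpec) -> np.ndarray:
    img, _ = render_eye(spec)
    return black_region_enhance(img)


class TestLocateIris:
    @pytest.mark.parametrize("offset", [-19.0, -8.0, 0.0, 8.0, 19.0])
    def test_recovers_known_center_and_radius(self, offset):
        spec = EyeRenderSpec(iris_offset=offset)
        img, true_iris = render_eye(spec)
        found = locate_iris(black_region_enhance(img))
        assert abs(found.center_x - true_iris.center_x) <= 2
        assert abs(found.center_y - true_iris.center_y) <= 2
        assert abs(found.radius - true_iris.radius) <= 0.2 * true_iris.radius

    def test_uniform_raster_has_no_iris(self):
        with pytest.raises(NoIrisError):
            locate_iris(np.full((36, 56), 128.0))

    def test_mirrored_eye_gives_mirrored_center(self):
        dark = _dark_channel(EyeRenderSpec(iris_offset=9))
        a = locate_iris(dark)
        b = locate_iris(dark[:, ::-1])
        assert b.center_x == pytest.approx(dark.shape[1] - 1 - a.center_x, abs=1)
        assert b.center_y == pytest.approx(a.center_y, abs=1)

    def test_agrees_with_hough_transform_oracle(self):
        # Independent circle detector on the same edge evidence.
        from skimage.transform import hough_circle, hough_circle_peaks

        spec = EyeRenderSpec(iris_offset=-6)
        img, _ = render_eye(spec)
        dark = black_region_enhance(img)
        found = locate_iris(dark)
        edges = prewitt_edges(dark) > 100
        radii = np.arange(4, 15)
        accum = hough_circle(edges, radii)
        _, cx, cy, r = hough_circle_peaks(accum, radii, total_num_peaks=1)
        assert abs(found.center_x - cx[0]) <= 2
        assert abs(found.center_y - cy[0]) <= 2
        assert abs(found.radius - r[0]) <= 2

    def test_deterministic(self):
        dark = _dark_channel(EyeRenderSpec(iris_offset=5, noise_sd=10, seed=3))
        a, b = locate_iris(dark), locate_iris(dark)
        assert a == b


class TestBrightnessProfile:
    def test_constant_raster_constant_profile(self):
        raster = np.full((5, 41), 128.0)
        prof = brightness_profile(raster, IrisLocation(20, 2, 10), 2.0)
        assert (prof.values == 128.0).all()

    def test_length_is_2_half_length_plus_1(self):
        raster = np.zeros((5, 41))
        prof = brightness_profile(raster, IrisLocation(20, 2, 10), 2.0)
        assert len(prof.values) == 41
        assert prof.center_index == 20

    def test_clipping_adjusts_center_index(self):
        raster = np.zeros((5, 30))
        prof = brightness_profile(raster, IrisLocation(5, 2, 10), 2.0)
        assert prof.center_index == 5  # window clipped at x = 0

    def test_dark_center_bright_flanks_minimum_at_center(self):
        raster = np.tile(np.abs(np.arange(41) - 20.0) + 10, (3, 1))
        prof = brightness_profile(raster, IrisLocation(20, 1, 5), 2.0)
        assert int(np.argmin(prof.values)) == prof.center_index

    def test_iris_outside_raster_rejected(self):
        with pytest.raises(ValueError):
            brightness_profile(np.zeros((5, 20)), IrisLocation(50, 2, 4), 2.0)


class TestScleraPeaks:
    def test_symmetric_profile_equal_peaks(self):
        values = np.array([200.0, 150, 20, 10, 20, 150, 200])
        sb = sclera_peaks(BrightnessProfile(values, 3), iris_radius=1)
        assert sb.LR == sb.RR == 200

    def test_matches_brute_force_max_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 255, 41)
        c, r = 20, 6
        sb = sclera_peaks(BrightnessProfile(values, c), iris_radius=r)
        assert sb.LR == max(values[i] for i in range(c - r))
        assert sb.RR == max(values[i] for i in range(c + r + 1, 41))

    def test_known_flank_maxima(self):
        values = np.zeros(21)
        values[2], values[18] = 200.0, 100.0
        sb = sclera_peaks(BrightnessProfile(values, 10), iris_radius=4)
        assert (sb.LR, sb.RR) == (200.0, 100.0)

    def test_profile_not_past_iris_is_degenerate(self):
        values = np.zeros(9)
        with pytest.raises(DegenerateProfileError):
            sclera_peaks(BrightnessProfile(values, 4), iris_radius=5)


class TestClassifyGaze:
    @pytest.mark.parametrize(
        "LR,RR,t,expected",
        [
            (100, 200, 0.85, GazeLabel.RIGHT),
            (200, 100, 0.85, GazeLabel.LEFT),
            (100, 100, 0.85, GazeLabel.CENTER),
            (170, 200, 0.85, GazeLabel.RIGHT),  # boundary 0.85 inclusive
            (200, 170, 0.85, GazeLabel.LEFT),
            (180, 200, 0.85, GazeLabel.CENTER),  # 0.9 > t
            (100, 100, 1.0, GazeLabel.CENTER),  # exact tie at t = 1
        ],
    )
    def test_rule_application(self, LR, RR, t, expected):
        assert classify_gaze(ScleraBrightness(LR, RR), t) is expected

    def test_both_zero_is_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            classify_gaze(ScleraBrightness(0, 0), 0.85)

    @pytest.mark.parametrize("t", [0.5, 0.85, 0.99])
    def test_partition_property_on_dense_grid(self, t):
        # Brute force: exactly one of the three conditions fires for every
        # positive (LR, RR) pair.
        grid = np.linspace(1, 255, 60)
        for LR in grid:
            for RR in grid:
                fires = [
                    LR / RR <= t,
                    RR / LR <= t,
                    min(LR, RR) / max(LR, RR) > t,
                ]
                assert sum(fires) == 1
                label = classify_gaze(ScleraBrightness(LR, RR), t)
                expected = [GazeLabel.RIGHT, GazeLabel.LEFT, GazeLabel.CENTER][
                    fires.index(True)
                ]
                assert label is expected


class TestClassifyEyeAndFrame:
    def test_monotone_crossing_no_oscillation(self):
        # Sweeping the iris across the eye produces one RIGHT run, one
        # CENTER run, one LEFT run (iris toward image-left = gaze at the
        # right half of the screen under the ratio rule).
        spec = EyeRenderSpec()
        d = int(spec.max_offset)
        seq = []
        for off in range(-d, d + 1):
            img, _ = render_eye(EyeRenderSpec(iris_offset=off))
            diag = classify_eye(img, Region(0, 0, *spec.image_size))
            assert diag.failure is None
            seq.append(diag.label)
        runs = [seq[0]]
        for lab in seq[1:]:
            if lab is not runs[-1]:
                runs.append(lab)
        assert runs == [GazeLabel.RIGHT, GazeLabel.CENTER, GazeLabel.LEFT]

    @pytest.mark.parametrize(
        "label", [GazeLabel.LEFT, GazeLabel.RIGHT, GazeLabel.CENTER]
    )
    def test_end_to_end_fixture_label(self, label):
        spec = EyeRenderSpec(iris_offset=iris_offset_for_label(label, EyeRenderSpec()))
        frame, truth = render_face(spec, spec)
        diag = classify_frame(frame, detection_from_truth(truth))
        assert diag.label is label
        assert all(e.label is label for e in diag.eyes)

    def test_missing_eye_is_distraction(self):
        frame, truth = render_face(EyeRenderSpec(), None)
        diag = classify_frame(frame, detection_from_truth(truth))
        assert diag.label is GazeLabel.DISTRACTION
        assert diag.reason == "both eyes not detected"

    def test_disagreeing_eyes_are_distraction(self):
        base = EyeRenderSpec()
        d = base.max_offset
        frame, truth = render_face(
            EyeRenderSpec(iris_offset=+d), EyeRenderSpec(iris_offset=-d)
        )
        diag = classify_frame(frame, detection_from_truth(truth))
        assert diag.label is GazeLabel.DISTRACTION
        assert diag.reason == "eyes disagree"

    @pytest.mark.parametrize(
        "label",
        [GazeLabel.LEFT, GazeLabel.RIGHT, GazeLabel.CENTER, GazeLabel.DISTRACTION],
    )
    def test_mirror_equivariance(self, label):
        # Horizontally mirroring a frame swaps LEFT and RIGHT and fixes
        # CENTER / DISTRACTION, end to end with bypassed detection.
        if label is GazeLabel.DISTRACTION:
            frame, truth = render_face(EyeRenderSpec(), None)
        else:
            off = iris_offset_for_label(label, EyeRenderSpec())
            spec = EyeRenderSpec(iris_offset=off)
            frame, truth = render_face(spec, spec)
        plain = classify_frame(frame, detection_from_truth(truth)).label
        mirrored = classify_frame(
            np.ascontiguousarray(frame[:, ::-1]),
            detection_from_truth(truth.mirrored(frame.shape[1])),
        ).label
        swap = {GazeLabel.LEFT: GazeLabel.RIGHT, GazeLabel.RIGHT: GazeLabel.LEFT}
        assert plain is label
        assert mirrored is swap.get(label, label)

    def test_uniform_eye_region_folds_into_distraction(self):
        frame = np.full((64, 96, 3), 128, dtype=np.uint8)
        from gazepref.detect import DetectionResult

        det = DetectionResult(
            left_eye=Region(4, 10, 30, 20), right_eye=Region(50, 10, 30, 20)
        )
        diag = classify_frame(frame, det)
        assert diag.label is GazeLabel.DISTRACTION
        assert diag.reason == "per-eye stage failed"
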