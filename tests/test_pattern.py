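import numpy as np
import pytest

from wingsym import (
    binarize_pattern,
    fit_ellipse,
    fit_hp_ellipse,
    hull_points,
    overlap_nuclei_estimate,
    pattern_eccentricity,
    preprocess_mask,
    project_stack,
    subtract_background,
)
from wingsym.pattern import EllipseFitError


def ellipse_points(a, b, theta=0.0, center=(0.0, 0.0), n=200):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return pts @ R.T + np.asarray(center)


def filled_ellipse_mask(a, b, theta=0.0, shape=(400, 400), center=None):
    h, w = shape
    cx, cy = center if center else ((w - 1) / 2, (h - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


class TestProjectStack:
    def test_single_plane_unchanged(self, rng):
        img = rng.random((8, 9))
        np.testing.assert_array_equal(project_stack(img[None]), img)

    def test_pixelwise_maximum(self):
        stack = np.stack([np.full((4, 4), 3.0), np.full((4, 4), 7.0)])
        np.testing.assert_array_equal(project_stack(stack), np.full((4, 4), 7.0))

    def test_grouped_blocks_of_five(self, rng):
        stack = rng.random((12, 5, 5))
        projections = project_stack(stack, group_size=5)
        assert len(projections) == 3
        np.testing.assert_array_equal(projections[2], stack[10:].max(axis=0))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            project_stack(np.empty((0, 4, 4)))


class TestSubtractBackground:
    def test_uniform_image_becomes_zero(self):
        img = np.full((64, 64), 10.0)
        np.testing.assert_array_equal(
            subtract_background(img, (0, 0), 30), np.zeros((64, 64))
        )

    def test_mean_subtraction_and_clamping(self):
        img = np.full((40, 40), 40.0)
        img[0, 0] = 100.0
        img[0, 1] = 30.0
        out = subtract_background(img, (5, 5), 30)
        assert out[0, 0] == pytest.approx(60.0)
        assert out[0, 1] == 0.0  # clamped

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            subtract_background(np.zeros((20, 20)), (0, 0), 30)


class TestBinarize:
    def test_threshold_is_strict_fraction_of_max(self):
        img = np.array([[250.0, 51.0, 49.0, 50.0]])
        mask = binarize_pattern(img, 0.20)  # threshold 50
        np.testing.assert_array_equal(mask, [[1, 1, 0, 0]])

    def test_fraction_zero_keeps_all_positive(self):
        img = np.array([[0.0, 0.1, 5.0]])
        np.testing.assert_array_equal(binarize_pattern(img, 0.0), [[0, 1, 1]])

    def test_constant_positive_image_fully_set(self):
        np.testing.assert_array_equal(
            binarize_pattern(np.full((3, 3), 7.0), 0.2), np.ones((3, 3))
        )

    def test_intensity_scale_invariance(self, rng):
        img = rng.random((30, 30)) * 100
        np.testing.assert_array_equal(binarize_pattern(img), binarize_pattern(img * 13.7))

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            binarize_pattern(np.zeros((5, 5)))


class TestPreprocessMask:
    def test_small_specks_removed_big_blob_kept(self):
        mask = np.zeros((80, 80), dtype=np.uint8)
        mask[10:50, 10:35] = 1  # 1000 px
        for r, c in ((2, 70), (70, 2), (75, 75)):
            mask[r : r + 2, c : c + 2] = 1  # specks, 4 px each
        out = preprocess_mask(mask, min_component_px=64, blur_kernel=1)
        assert out[2, 70] == 0 and out[70, 2] == 0 and out[75, 75] == 0
        assert out[30, 20] == 1

    def test_identity_parameters(self, rng):
        mask = (rng.random((20, 20)) > 0.4).astype(np.uint8)
        np.testing.assert_array_equal(
            preprocess_mask(mask, min_component_px=0, blur_kernel=1), mask
        )

    def test_keep_largest_tie_takes_first_in_scan_order(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:7, 2:7] = 1  # first in scan order
        mask[20:25, 20:25] = 1  # equal size
        out = preprocess_mask(mask, min_component_px=0, blur_kernel=1, keep_largest=True)
        assert out[4, 4] == 1 and out[22, 22] == 0

    def test_empty_after_cleanup_rejected(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[0, 0] = 1
        with pytest.raises(ValueError, match="empty"):
            preprocess_mask(mask, min_component_px=64)

    def test_blur_smooths_single_pixel_protrusion(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[10:30, 10:30] = 1
        mask[5, 20] = 1  # isolated protrusion far from the block
        out = preprocess_mask(mask, min_component_px=0, blur_kernel=5)
        assert out[5, 20] == 0
        assert out[20, 20] == 1


class TestHullPoints:
    def test_filled_rectangle_hull_is_corners(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[10:21, 5:16] = 1
        hull = hull_points(mask)
        assert len(hull) == 4
        assert {tuple(p) for p in hull} == {(5, 10), (15, 10), (15, 20), (5, 20)}

    def test_hull_counterclockwise_in_xy(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[10:21, 5:16] = 1
        hull = hull_points(mask)
        x, y = hull[:, 0], hull[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0

    def test_single_pixel_rejected(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[5, 5] = 1
        with pytest.raises(ValueError):
            hull_points(mask)

    def test_collinear_pixels_rejected(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3, 2:8] = 1
        with pytest.raises(ValueError):
            hull_points(mask)

    def test_interior_pixels_do_not_affect_hull(self):
        mask = filled_ellipse_mask(30, 20, shape=(100, 100))
        punched = mask.copy()
        punched[50, 50] = 0  # remove an interior pixel
        np.testing.assert_array_equal(hull_points(mask), hull_points(punched))


class TestFitEllipse:
    def test_unit_circle(self):
        e = fit_ellipse(ellipse_points(1.0, 1.0))
        assert e.a == pytest.approx(1.0, abs=1e-6)
        assert e.b == pytest.approx(1.0, abs=1e-6)
        assert e.e == pytest.approx(0.0, abs=1e-3)

    def test_known_ellipse_eccentricity(self):
        e = fit_ellipse(ellipse_points(2.0, 1.0, np.deg2rad(30.0), center=(40.0, -7.0)))
        assert e.e == pytest.approx(0.866025, abs=1e-6)
        assert e.a == pytest.approx(2.0, abs=1e-6)
        assert e.b == pytest.approx(1.0, abs=1e-6)
        assert e.center[0] == pytest.approx(40.0, abs=1e-6)
        assert e.center[1] == pytest.approx(-7.0, abs=1e-6)
        assert e.theta == pytest.approx(np.deg2rad(30.0), abs=1e-6)

    def test_zero_residual_for_exact_points(self):
        pts = ellipse_points(3.0, 2.0, 0.7, center=(5.0, 5.0), n=40)
        e = fit_ellipse(pts)
        # implicit-equation residual in the ellipse's own frame
        rel = pts - np.asarray(e.center)
        c, s = np.cos(e.theta), np.sin(e.theta)
        u = rel[:, 0] * c + rel[:, 1] * s
        v = -rel[:, 0] * s + rel[:, 1] * c
        resid = (u / e.a) ** 2 + (v / e.b) ** 2 - 1.0
        assert np.max(np.abs(resid)) < 1e-9

    def test_a_ge_b_normalization(self):
        # generate with the long axis along y so the raw fit would give b > a
        e = fit_ellipse(ellipse_points(1.0, 2.0))
        assert e.a >= e.b
        assert e.a == pytest.approx(2.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(EllipseFitError, match="5"):
            fit_ellipse(ellipse_points(2.0, 1.0, n=4))


class TestPatternEccentricity:
    def test_filled_disc_is_nearly_circular(self):
        mask = filled_ellipse_mask(150, 150, shape=(340, 340))
        assert pattern_eccentricity(mask).e <= 0.1

    def test_filled_ellipse_recovers_eccentricity(self):
        mask = filled_ellipse_mask(200, 120, shape=(440, 440))
        assert pattern_eccentricity(mask).e == pytest.approx(0.8, abs=0.02)

    def test_rotation_invariance(self):
        e0 = pattern_eccentricity(filled_ellipse_mask(200, 120, shape=(440, 440))).e
        e45 = pattern_eccentricity(
            filled_ellipse_mask(200, 120, theta=np.pi / 4, shape=(440, 440))
        ).e
        assert e45 == pytest.approx(e0, abs=0.01)

    def test_translation_and_downscale_invariance(self):
        base = pattern_eccentricity(filled_ellipse_mask(200, 120, shape=(440, 440))).e
        moved = pattern_eccentricity(
            filled_ellipse_mask(200, 120, shape=(460, 460), center=(230, 215))
        ).e
        half = pattern_eccentricity(filled_ellipse_mask(100, 60, shape=(240, 240))).e
        assert moved == pytest.approx(base, abs=0.02)
        assert half == pytest.approx(0.8, abs=0.02)


class TestHpEllipse:
    def test_eight_exact_clicks_recover_parameters(self):
        pts = ellipse_points(120.0, 80.0, 0.4, center=(250.0, 260.0), n=8)
        e = fit_hp_ellipse(pts)
        assert e.a == pytest.approx(120.0, abs=1e-6)
        assert e.b == pytest.approx(80.0, abs=1e-6)
        assert e.theta == pytest.approx(0.4, abs=1e-6)

    def test_five_points_determine_the_conic(self):
        pts = ellipse_points(3.0, 2.0, 0.2, n=5)
        e = fit_hp_ellipse(pts)
        assert e.a == pytest.approx(3.0, abs=1e-6)

    def test_four_points_rejected(self):
        with pytest.raises(EllipseFitError):
            fit_hp_ellipse(ellipse_points(3.0, 2.0, n=4))


class TestOverlapNuclei:
    def test_thousand_pixels_is_five_nuclei(self):
        a = np.zeros((50, 50), dtype=np.uint8)
        b = np.zeros((50, 50), dtype=np.uint8)
        a[:20, :50] = 1
        b[:20, :50] = 1
        assert overlap_nuclei_estimate(a, b) == 5.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        a[:5] = 1
        b[5:] = 1
        assert overlap_nuclei_estimate(a, b) == 0.0

    def test_fractional_estimate_not_rounded(self):
        a = np.zeros((20, 20), dtype=np.uint8)
        a.ravel()[:199] = 1
        assert overlap_nuclei_estimate(a, a) == pytest.approx(0.995)

    def test_symmetric_and_monotone(self, rng):
        a = (rng.random((30, 30)) > 0.5).astype(np.uint8)
        b = (rng.random((30, 30)) > 0.5).astype(np.uint8)
        assert overlap_nuclei_estimate(a, b) == overlap_nuclei_estimate(b, a)
        grown = b | a
        assert overlap_nuclei_estimate(a, grown) >= overlap_nuclei_estimate(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            overlap_nuclei_estimate(np.zeros((3, 3)), np.zeros((4, 4)))
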