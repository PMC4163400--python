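"""Entropy thresholding, ray casting, threshold-field refinement, contour smoothing."""

import numpy as np
import pytest
from scipy import ndimage

from lungmorph import errors
from lungmorph.metrics import dsc
from lungmorph.outer_contour import (
    cast_rays,
    entropy_threshold,
    fit_threshold_field,
    refine_outer_mask,
    segment_global,
    smooth_contour,
)


def kapur_oracle(values):
    """Exhaustive maximum-entropy threshold search (independent of the implementation)."""
    hist = np.bincount(values.astype(int).ravel(), minlength=256).astype(float)
    best_t, best_e = None, -np.inf
    for t in range(256):
        lo, hi = hist[: t + 1], hist[t + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            continue

        def H(h):
            p = h[h > 0] / h.sum()
            return float(-(p * np.log2(p)).sum())

        e = H(lo) + H(hi)
        if e > best_e:
            best_e, best_t = e, t
    return best_t


class TestEntropyThreshold:
    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(50):
            img = rng.integers(0, 256, (32, 32)).astype(float)
            assert entropy_threshold(img) == kapur_oracle(img)

    def test_bimodal_halves_tie_breaks_to_smallest(self):
        img = np.array([[50.0] * 8 + [200.0] * 8])
        assert entropy_threshold(img) == 50

    def test_uniform_histogram_splits_at_midpoint(self):
        img = np.tile(np.arange(256.0), (4, 1))
        assert entropy_threshold(img) == 127

    def test_two_pixel_extremes(self):
        assert entropy_threshold(np.array([[0.0, 255.0]])) == 0

    def test_duplication_invariance(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(float)
        doubled = np.vstack([img, img])
        assert entropy_threshold(img) == entropy_threshold(doubled)

    def test_single_intensity_rejected(self):
        with pytest.raises(errors.DegenerateHistogramError):
            entropy_threshold(np.full((8, 8), 42.0))

    def test_roi_restriction(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(float)
        roi = np.zeros((16, 16), bool)
        roi[:8] = True
        assert entropy_threshold(img, roi) == kapur_oracle(img[:8])


class TestSegmentGlobal:
    def test_bright_disc_on_dark_background(self, rng):
        rr, cc = np.mgrid[0:96, 0:96]
        truth = (rr - 48) ** 2 + (cc - 48) ** 2 <= 30**2
        img = np.where(truth, 200.0, 30.0) + rng.normal(0, 3, (96, 96))
        mask = segment_global(img)
        assert dsc(mask, truth) >= 99.0

    def test_dark_disc_on_bright_background(self, rng):
        rr, cc = np.mgrid[0:96, 0:96]
        truth = (rr - 48) ** 2 + (cc - 48) ** 2 <= 30**2
        img = np.where(truth, 40.0, 220.0) + rng.normal(0, 3, (96, 96))
        mask = segment_global(img)
        assert dsc(mask, truth) >= 99.0

    def test_constant_image_fails(self):
        with pytest.raises(errors.SegmentationFailureError):
            segment_global(np.full((32, 32), 7.0))

    def test_interior_hole_is_filled(self):
        rr, cc = np.mgrid[0:96, 0:96]
        disc = (rr - 48) ** 2 + (cc - 48) ** 2 <= 30**2
        hole = (rr - 48) ** 2 + (cc - 48) ** 2 <= 10**2
        img = np.where(disc & ~hole, 200.0, 30.0)
        mask = segment_global(img)
        assert dsc(mask, disc) >= 99.0


class TestCastRays:
    def test_exactly_eight_rays_at_45_degree_steps(self, disc_mask):
        fan = cast_rays(disc_mask)
        assert len(fan.angles) == 8
        assert np.allclose(np.diff(fan.angles), 45.0)

    def test_centered_disc_distances_equal_radius(self, disc_mask):
        fan = cast_rays(disc_mask)
        assert np.allclose(fan.distances, 20.0, atol=1.0)
        assert fan.mean_distance == pytest.approx(np.mean(fan.distances))

    def test_centered_square_axial_and_diagonal_distances(self):
        mask = np.zeros((64, 64), bool)
        a = 15
        mask[32 - a : 32 + a + 1, 32 - a : 32 + a + 1] = True
        fan = cast_rays(mask)
        d = np.array(fan.distances)
        axial = d[[0, 2, 4, 6]]
        diag = d[[1, 3, 5, 7]]
        assert np.allclose(axial, a, atol=1.0)
        assert np.allclose(diag, a * np.sqrt(2), atol=1.5)

    def test_centroid_outside_foreground_rejected(self):
        mask = np.zeros((40, 40), bool)
        # symmetric pair of blobs: centroid lands in the empty middle
        mask[5:12, 5:12] = True
        mask[28:35, 28:35] = True
        with pytest.raises(errors.RayOriginError):
            cast_rays(mask)

    def test_intersections_on_mask_boundary(self, disc_mask):
        fan = cast_rays(disc_mask)
        for (r, c), dist in zip(fan.intersections, fan.distances):
            radius = np.hypot(r - fan.centroid[0], c - fan.centroid[1])
            assert radius == pytest.approx(dist, abs=1e-6)


class TestThresholdField:
    def test_field_matches_control_points(self, rng):
        pts = [(10.0, 12.0), (10.0, 50.0), (50.0, 12.0), (50.0, 50.0), (30.0, 30.0)]
        vals = [100.0, 120.0, 90.0, 140.0, 110.0]
        field = fit_threshold_field(pts, vals, (64, 64))
        for (r, c), v in zip(pts, vals):
            assert abs(field.values[int(r), int(c)] - v) <= 1.0

    def test_field_is_smooth(self):
        pts = [(10.0, 10.0), (10.0, 54.0), (54.0, 10.0), (54.0, 54.0)]
        vals = [80.0, 120.0, 100.0, 140.0]
        field = fit_threshold_field(pts, vals, (64, 64))
        # continuity: neighbor-to-neighbor steps stay far below a level jump
        assert np.abs(np.diff(field.values, axis=0)).max() < 20.0
        assert np.abs(np.diff(field.values, axis=1)).max() < 20.0

    def test_refinement_reduces_to_global_for_uniform_contrast(self, rng):
        rr, cc = np.mgrid[0:128, 0:128]
        truth = (rr - 64) ** 2 + (cc - 64) ** 2 <= 45**2
        img = np.where(truth, 190.0, 40.0) + rng.normal(0, 4, (128, 128))
        global_mask = segment_global(img)
        refined = refine_outer_mask(img, global_mask)
        assert dsc(refined, global_mask) >= 99.0

    def test_refinement_beats_global_under_illumination_ramp(self, rng):
        rr, cc = np.mgrid[0:128, 0:192]
        truth = (rr - 64) ** 2 + (cc - 96) ** 2 <= 50**2
        ramp = np.linspace(-55, 55, 192)[None, :]
        img = np.where(truth, 160.0, 60.0) + ramp + rng.normal(0, 3, (128, 192))
        img = np.clip(img, 0, 255)
        global_mask = segment_global(img)
        refined = refine_outer_mask(img, global_mask)
        assert dsc(refined, truth) > dsc(global_mask, truth)


class TestSmoothContour:
    def test_large_disc_nearly_unchanged(self, disc_mask):
        out = smooth_contour(disc_mask, 1.0)
        assert dsc(out, disc_mask) >= 98.0

    def test_square_loses_area_and_rounds_corners(self):
        mask = np.zeros((64, 64), bool)
        mask[20:45, 20:45] = True
        out = smooth_contour(mask, 3.0)
        assert out.sum() < mask.sum()
        assert not out[20, 20]  # corner rounded away

    def test_one_pixel_spur_removed(self, disc_mask):
        spur = disc_mask.copy()
        spur[32, 52:60] = True  # 1-px-wide whisker off the disc
        out = smooth_contour(spur, 2.0)
        assert not out[32, 55:60].any()

    def test_oversmoothing_raises(self):
        mask = np.zeros((32, 32), bool)
        mask[15:17, 15:17] = True
        with pytest.raises(errors.OverSmoothingError):
            smooth_contour(mask, 6.0)
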