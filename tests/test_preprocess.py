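import numpy as np
import pytest

from plantar.arch import compute_ai, segment_thirds
from plantar.io import FootprintImage
from plantar.preprocess import (
    ColorRange,
    DetectionError,
    FOOT_RANGE,
    FootObject,
    RED_RANGE,
    RotationSpec,
    center_feet,
    contact_mask_from_image,
    contrast_normalize,
    detect_foot_objects,
    estimate_rotation_angle,
    preprocess_frame,
    remove_toes,
    remove_toes_grid,
    rotate_image,
    rotation_matrix,
)

def _blob_image(offsets=((0, 0), (0, 0)), size=200, blob=30):
    """White image with one solid blue blob per half, optionally offset."""
    pixels = np.full((size, size, 3), 255, dtype=np.uint8)
    centers = [(size // 2, size // 4), (size // 2, 3 * size // 4)]
    for (dr, dc), (r, c) in zip(offsets, centers):
        rr = slice(r + dr - blob // 2, r + dr + blob // 2)
        cc = slice(c + dc - blob // 2, c + dc + blob // 2)
        pixels[rr, cc] = (0, 0, 255)
    return FootprintImage(pixels=pixels)


class TestColorRange:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ColorRange(h_min=50, h_max=40)
        with pytest.raises(ValueError):
            ColorRange(v_min=-1)

    def test_dark_pixels_fall_outside_foot_range(self):
        pixels = np.full((10, 10, 3), 255, dtype=np.uint8)
        pixels[2, 2] = (0, 0, 200)  # blue, bright
        pixels[3, 3] = (0, 0, 20)  # blue but V < 30
        mask = FOOT_RANGE.mask(pixels)
        assert mask[2, 2] and not mask[3, 3]

    def test_white_background_excluded_by_saturation(self):
        pixels = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert not FOOT_RANGE.mask(pixels).any()


class TestDetectFootObjects:
    def test_two_blobs_assigned_by_midline(self):
        left, right = detect_foot_objects(_blob_image())
        assert left.side == "left" and right.side == "right"
        assert left.centroid[1] < right.centroid[1]
        assert not (left.mask & right.mask).any()

    def test_background_only_image_fails_with_count(self):
        empty = FootprintImage(pixels=np.full((64, 64, 3), 255, dtype=np.uint8))
        with pytest.raises(DetectionError, match="0"):
            detect_foot_objects(empty)

    def test_single_half_occupied_fails(self):
        img = _blob_image()
        img.pixels[:, 100:] = 255  # wipe the right half
        with pytest.raises(DetectionError):
            detect_foot_objects(img)


class TestCenterFeet:
    def test_offset_blob_is_recentered(self):
        img = _blob_image(offsets=((30, -20), (0, 0)))
        centered = center_feet(img)
        left, _ = detect_foot_objects(centered)
        assert left.bbox_center == pytest.approx((99.5, 49.5), abs=1.0)

    def test_idempotent(self):
        img = _blob_image(offsets=((13, 7), (-9, 4)))
        once = center_feet(img)
        twice = center_feet(once)
        assert np.array_equal(once.pixels, twice.pixels)


class TestRotation:
    def test_rotation_matrix_quarter_turn(self):
        assert rotation_matrix(90) @ np.array([1.0, 0.0]) == pytest.approx([0.0, 1.0])

    def test_axis_aligned_rectangle_has_zero_angle(self):
        mask = np.zeros((100, 50), dtype=bool)
        mask[20:80, 15:35] = True
        foot = FootObject(mask=mask, bbox=(20, 15, 80, 35), centroid=(49.5, 24.5), side="left")
        assert estimate_rotation_angle(foot).theta == 0.0

    def test_mirrored_mask_negates_angle(self):
        mask = np.zeros((100, 60), dtype=bool)
        for i in range(60):  # slanted bar
            mask[20 + i, 20 + i // 6: 26 + i // 6] = True
        foot = FootObject(mask=mask, bbox=(20, 20, 80, 36), centroid=(50, 28), side="left")
        theta = estimate_rotation_angle(foot).theta
        mirrored = FootObject(
            mask=mask[:, ::-1], bbox=(20, 60 - 36, 80, 60 - 20),
            centroid=(50, 60 - 28), side="right",
        )
        assert estimate_rotation_angle(mirrored).theta == pytest.approx(-theta, abs=1e-9)

    def test_zero_rotation_is_identity(self, clean_image):
        spec = RotationSpec(theta=0.0, center=(459, 459))
        assert np.array_equal(rotate_image(clean_image, spec).pixels, clean_image.pixels)

    def test_rotate_there_and_back(self, clean_image):
        center = (458.5, 458.5)
        there = rotate_image(clean_image, RotationSpec(theta=12.0, center=center))
        back = rotate_image(there, RotationSpec(theta=-12.0, center=center))
        diff = np.abs(back.pixels.astype(float) - clean_image.pixels.astype(float))
        assert diff.mean() <= 2.0

    def test_known_rotation_recovered(self, clean_image):
        """A programmatically rotated footprint reads back its angle (+-1 deg)."""
        h, w = clean_image.shape
        left0, _ = detect_foot_objects(clean_image)
        base = estimate_rotation_angle(left0).theta
        half = FootprintImage(pixels=clean_image.pixels[:, : w // 2].copy(), side="left")
        rotated = rotate_image(
            half, RotationSpec(theta=10.0, center=((h - 1) / 2, (w // 2 - 1) / 2))
        )
        px = clean_image.pixels.copy()
        px[:, : w // 2] = rotated.pixels
        left, _ = detect_foot_objects(FootprintImage(pixels=px))
        assert estimate_rotation_angle(left).theta - base == pytest.approx(10.0, abs=1.0)


class TestRemoveToes:
    def test_toe_blobs_removed_sole_intact(self, clean_image):
        w = clean_image.shape[1]
        half = FootprintImage(pixels=clean_image.pixels[:, : w // 2].copy(), side="left")
        before = FOOT_RANGE.mask(half.pixels)
        after_img = remove_toes(half)
        after = FOOT_RANGE.mask(after_img.pixels)
        assert after.sum() < before.sum()  # toes gone
        # what remains is a single connected sole region spanning the heel
        from skimage.measure import label

        assert label(after, connectivity=2).max() == 1
        rows_before = np.flatnonzero(before.any(axis=1))
        rows_after = np.flatnonzero(after.any(axis=1))
        assert rows_after[-1] == rows_before[-1]  # heel end untouched

    def test_never_adds_pixels(self, clean_image):
        w = clean_image.shape[1]
        half = FootprintImage(pixels=clean_image.pixels[:, w // 2:].copy(), side="right")
        before = FOOT_RANGE.mask(half.pixels)
        after = FOOT_RANGE.mask(remove_toes(half).pixels)
        assert not (after & ~before).any()

    def test_compact_footprint_unchanged(self):
        # everything within R of the high-pressure centroid: nothing removed
        values = np.zeros((48, 48))
        values[18:32, 10:13] = 50.0
        values[32, 11] = 50.0  # rounded heel tip defines the radius
        values[24:26, 10:13] = 150.0
        out = remove_toes_grid(values)
        assert np.array_equal(out, values)

    def test_outside_disk_becomes_background(self, clean_image):
        """AND semantics: colored pixel & excluded mask -> background."""
        w = clean_image.shape[1]
        half = FootprintImage(pixels=clean_image.pixels[:, : w // 2].copy(), side="left")
        before = FOOT_RANGE.mask(half.pixels)
        out = remove_toes(half)
        removed = before & ~FOOT_RANGE.mask(out.pixels)
        assert removed.any()
        assert (out.pixels[removed] == 255).all()

    def test_no_high_pressure_region_is_an_error(self):
        pixels = np.full((100, 100, 3), 255, dtype=np.uint8)
        pixels[40:60, 40:60] = (0, 0, 255)  # blue only, nothing red
        with pytest.raises(DetectionError, match="red"):
            remove_toes(FootprintImage(pixels=pixels))


class TestContrastNormalize:
    def test_two_point_example(self):
        normalized, norm = contrast_normalize(np.array([0.0, 2.0]))
        assert normalized == pytest.approx([-1.0, 1.0])
        assert norm.x_mean == 1.0 and norm.std == 1.0

    def test_constant_input_maps_to_zeros(self):
        normalized, _ = contrast_normalize(np.full(10, 3.7))
        assert (normalized == 0).all()

    def test_output_is_standardized(self, rng):
        normalized, _ = contrast_normalize(rng.normal(10, 3, size=(30, 30)))
        assert abs(normalized.mean()) < 1e-9
        assert abs(normalized.std() - 1) < 1e-9

    def test_normalizer_reapplies_training_statistics(self, rng):
        x = rng.normal(5, 2, 100)
        _, norm = contrast_normalize(x)
        held_out = np.array([5.0])
        assert norm.apply(held_out) == pytest.approx((5.0 - norm.x_mean) / norm.std)


class TestPipelineInvariance:
    def test_centering_preserves_arch_index(self, clean_image):
        w = clean_image.shape[1]
        centered = center_feet(clean_image)
        for sl in (slice(0, w // 2), slice(w // 2, w)):
            ai_before = compute_ai(
                segment_thirds(contact_mask_from_image(clean_image)[:, sl])
            ).ai
            ai_after = compute_ai(
                segment_thirds(contact_mask_from_image(centered)[:, sl])
            ).ai
            assert ai_after == pytest.approx(ai_before, abs=1e-12)

    def test_rotation_correction_restores_arch_index(self, clean_image):
        """Rotating by a known angle and running pose correction changes the
        measured AI by at most 0.01 relative to the unrotated chain."""
        w = clean_image.shape[1]
        h = clean_image.shape[0]

        def chain_ai(image):
            proc = preprocess_frame(image)
            mask = contact_mask_from_image(proc)
            return [
                compute_ai(segment_thirds(mask[:, sl])).ai
                for sl in (slice(0, w // 2), slice(w // 2, w))
            ]

        base = chain_ai(clean_image)
        px = clean_image.pixels.copy()
        for theta, sl in ((8.0, slice(0, w // 2)), (-6.0, slice(w // 2, w))):
            half = FootprintImage(pixels=clean_image.pixels[:, sl].copy())
            px[:, sl] = rotate_image(
                half, RotationSpec(theta=theta, center=((h - 1) / 2, (w // 2 - 1) / 2))
            ).pixels
        rotated = chain_ai(FootprintImage(pixels=px))
        assert rotated == pytest.approx(base, abs=0.01)
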