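"""Footprint image preprocessing: detection, centering, pose correction, toe removal.

The chain mirrors how standing-pressure exports are prepared for scoring and
learning: the two foot objects are detected in HSV space against the white
background, moved to the centers of their image halves, rotated so the
medial line of each foot is vertical, and cropped to the toe-less footprint
by a heel-anchored circular mask around the high-pressure region.  Contrast
normalization ((x - mean) / std) is shared by the image and numeric branches.

Color ranges use the half-degree hue convention (H in 0-180, S and V in
0-255): the whole pressure colormap falls in H 0-120 and the high-pressure
(red) band in H 0-40, with S >= 30 excluding the white background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import measure
from skimage.transform import rotate as _sk_rotate

from .io import BACKGROUND_RGB, FootprintImage


class DetectionError(RuntimeError):
    pass


@dataclass
class ColorRange:
    """Inclusive HSV box on the half-degree hue scale (H 0-180, S/V 0-255)."""

    h_min: float = 0
    h_max: float = 180
    s_min: float = 0
    s_max: float = 255
    v_min: float = 0
    v_max: float = 255

    def __post_init__(self) -> None:
        for lo, hi, top in (
            (self.h_min, self.h_max, 180),
            (self.s_min, self.s_max, 255),
            (self.v_min, self.v_max, 255),
        ):
            if not (0 <= lo <= hi <= top):
                raise ValueError(f"invalid channel range [{lo}, {hi}] (max {top})")

    def mask(self, pixels: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the HSV box."""
        hsv = skcolor.rgb2hsv(np.asarray(pixels, dtype=float) / 255.0)
        h = hsv[..., 0] * 180.0
        s = hsv[..., 1] * 255.0
        v = hsv[..., 2] * 255.0
        return (
            (h >= self.h_min) & (h <= self.h_max)
            & (s >= self.s_min) & (s <= self.s_max)
            & (v >= self.v_min) & (v <= self.v_max)
        )


#: foot-object range: everything in the pressure colormap except background
FOOT_RANGE = ColorRange(h_min=0, h_max=120, s_min=30, s_max=255, v_min=30, v_max=255)
#: high-pressure (red) range used to anchor toe removal
RED_RANGE = ColorRange(h_min=0, h_max=40, s_min=30, s_max=255, v_min=30, v_max=255)

#: connected components smaller than this (pixels) are treated as speckle
MIN_COMPONENT_PX = 50


@dataclass
class FootObject:
    """A detected foot: full-frame mask plus bbox/centroid bookkeeping."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # top, left, bottom, right (exclusive)
    centroid: tuple[float, float]  # row, col
    side: str

    @property
    def bbox_center(self) -> tuple[float, float]:
        t, l, b, r = self.bbox
        return ((t + b - 1) / 2.0, (l + r - 1) / 2.0)


@dataclass
class RotationSpec:
    """Signed rotation in degrees, + counterclockwise, about ``center`` (row, col)."""

    theta: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(self.theta) > 90:
            raise ValueError(f"|theta| must be <= 90 deg, got {self.theta}")


@dataclass
class ToeMaskSpec:
    """Disk kept by toe removal: centered on the high-pressure centroid,
    radius equal to the centroid-to-heel-end distance."""

    center: tuple[float, float]
    radius_R: float

    def __post_init__(self) -> None:
        if self.radius_R <= 0:
            raise ValueError("radius_R must be positive")


@dataclass
class Normalizer:
    """Frozen contrast-normalization statistics, reusable on held-out data."""

    x_mean: float
    std: float

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.std == 0:
            return np.zeros_like(x)
        return (x - self.x_mean) / self.std


def detect_foot_objects(
    image: FootprintImage,
    color_range: ColorRange = FOOT_RANGE,
    min_component_px: int = MIN_COMPONENT_PX,
) -> tuple[FootObject, FootObject]:
    """Detect the left and right foot objects in a both-feet image.

    Components smaller than ``min_component_px`` are suppressed as sensor
    speckle.  Components are assigned to the side of the image half
    containing their centroid and merged per half (a footprint export can
    split into sole and toe components); each half must contain exactly one
    merged foot object.
    """
    raw = color_range.mask(image.pixels)
    labeled = measure.label(raw, connectivity=2)
    regions = [r for r in measure.regionprops(labeled) if r.area >= min_component_px]
    if not regions:
        raise DetectionError(
            "expected 2 foot objects after speckle suppression, found 0"
        )
    w = image.pixels.shape[1]
    per_side: dict[str, np.ndarray] = {}
    for region in regions:
        side = "left" if region.centroid[1] < w / 2 else "right"
        mask = labeled == region.label
        per_side[side] = mask | per_side.get(side, np.zeros_like(mask))
    if set(per_side) != {"left", "right"}:
        raise DetectionError(
            f"expected 2 foot objects (one per half), found {len(per_side)} "
            f"occupied halves from {len(regions)} components"
        )
    feet = {}
    for side, mask in per_side.items():
        rr, cc = np.nonzero(mask)
        feet[side] = FootObject(
            mask=mask,
            bbox=(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1),
            centroid=(float(rr.mean()), float(cc.mean())),
            side=side,
        )
    return feet["left"], feet["right"]


def _half_center(shape: tuple[int, int], side: str) -> tuple[float, float]:
    h, w = shape
    col = (w / 2 - 1) / 2.0 if side == "left" else w / 2 + (w / 2 - 1) / 2.0
    return ((h - 1) / 2.0, col)


def center_feet(
    image: FootprintImage, color_range: ColorRange = FOOT_RANGE
) -> FootprintImage:
    """Translate each foot so its bbox center sits at the center of its half.

    Pixel content is moved by integer offsets (no resampling); exposed areas
    become background.  The operation is idempotent to within one pixel.
    """
    left, right = detect_foot_objects(image, color_range)
    out = np.full_like(image.pixels, 255)
    out[..., 0], out[..., 1], out[..., 2] = BACKGROUND_RGB
    for foot in (left, right):
        target = _half_center(image.shape, foot.side)
        cr, cc = foot.bbox_center
        dr = int(round(target[0] - cr))
        dc = int(round(target[1] - cc))
        src_rows, src_cols = np.nonzero(foot.mask)
        dst_rows = src_rows + dr
        dst_cols = src_cols + dc
        ok = (
            (dst_rows >= 0) & (dst_rows < out.shape[0])
            & (dst_cols >= 0) & (dst_cols < out.shape[1])
        )
        out[dst_rows[ok], dst_cols[ok]] = image.pixels[src_rows[ok], src_cols[ok]]
    return FootprintImage(pixels=out, side=image.side)


def _medial_point(mask: np.ndarray, rows: np.ndarray, side: str) -> tuple[int, int]:
    """Medial-most mask pixel within the given rows.

    Medial = right edge for a left foot, left edge for a right foot.  Ties on
    the extreme column break to the pixel nearest the row-range center.
    """
    sub = mask[rows]
    rr, cc = np.nonzero(sub)
    if rr.size == 0:
        raise DetectionError("foot mask empty in one half; cannot estimate rotation")
    target_col = cc.max() if side == "left" else cc.min()
    at = rr[cc == target_col]
    mid = (rows.size - 1) / 2.0
    best = at[np.argmin(np.abs(at - mid))]
    return int(rows[best]), int(target_col)


def estimate_rotation_angle(foot: FootObject) -> RotationSpec:
    """Angle between the foot's medial line and the image vertical.

    The mask is split into upper and lower parts at its bbox row center; the
    medial line joins the medial-most pixel of each part.  Positive theta
    means the foot leans counterclockwise (top toward the lateral side of a
    left image half).

    When the mask decomposes into several components (detached toe blobs on
    a coarse raster), the medial line is estimated on the largest component
    — the sole — whose medial bulges (ball and heel) carry the line.
    """
    labeled = measure.label(foot.mask, connectivity=2)
    if labeled.max() > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        mask = labeled == (1 + int(np.argmax(sizes)))
        rr = np.nonzero(mask.any(axis=1))[0]
        t, b = int(rr[0]), int(rr[-1]) + 1
        foot = FootObject(mask=mask, bbox=(t, foot.bbox[1], b, foot.bbox[3]),
                          centroid=foot.centroid, side=foot.side)
    t, _, b, _ = foot.bbox
    mid = (t + b) // 2
    upper = np.arange(t, mid)
    lower = np.arange(mid, b)
    if upper.size == 0 or lower.size == 0:
        raise DetectionError("foot mask too short to split into halves")
    r_up, c_up = _medial_point(foot.mask, upper, foot.side)
    r_low, c_low = _medial_point(foot.mask, lower, foot.side)
    if r_low == r_up:
        raise DetectionError("degenerate medial line (zero vertical extent)")
    theta = float(np.degrees(np.arctan2(c_low - c_up, r_low - r_up)))
    return RotationSpec(theta=theta, center=foot.centroid)


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """2-D rotation matrix [[cos, -sin], [sin, cos]] for theta in degrees."""
    rad = np.radians(theta_deg)
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[c, -s], [s, c]])


def rotate_image(image: FootprintImage, spec: RotationSpec) -> FootprintImage:
    """Rotate by ``spec.theta`` degrees (counterclockwise) about ``spec.center``.

    Exposed pixels are filled with the white background.
    """
    if abs(spec.theta) < 1e-12:
        return FootprintImage(pixels=image.pixels.copy(), side=image.side)
    rotated = _sk_rotate(
        image.pixels.astype(float),
        angle=spec.theta,
        center=(spec.center[1], spec.center[0]),  # skimage expects (col, row)
        resize=False,
        order=1,
        mode="constant",
        cval=255.0,
        preserve_range=True,
    )
    return FootprintImage(
        pixels=np.clip(np.round(rotated), 0, 255).astype(np.uint8), side=image.side
    )


def correct_rotation(
    image: FootprintImage, color_range: ColorRange = FOOT_RANGE
) -> FootprintImage:
    """Rotate each foot so its medial line is vertical.

    Each image half is rotated independently (by -theta about the half
    center) and the halves are reassembled.
    """
    left, right = detect_foot_objects(image, color_range)
    h, w = image.shape
    out = np.empty_like(image.pixels)
    for foot, cols in ((left, slice(0, w // 2)), (right, slice(w // 2, w))):
        spec = estimate_rotation_angle(foot)
        half = FootprintImage(pixels=image.pixels[:, cols].copy(), side=foot.side)
        half_center = ((h - 1) / 2.0, (half.pixels.shape[1] - 1) / 2.0)
        corrected = rotate_image(half, RotationSpec(theta=-spec.theta, center=half_center))
        out[:, cols] = corrected.pixels
    return FootprintImage(pixels=out, side=image.side)


def toe_mask_spec(
    foot_mask: np.ndarray, red_mask: np.ndarray
) -> ToeMaskSpec:
    """Disk spec for toe removal from the foot and high-pressure masks.

    Center = centroid of the high-pressure region; R = distance from the
    center to the heel end (bottom-most foot pixel, at the column nearest the
    foot axis among the bottom row's pixels).
    """
    if not red_mask.any():
        raise DetectionError(
            "no high-pressure (red-range) region found; widen the red color range"
        )
    rr, cc = np.nonzero(red_mask)
    center = (float(rr.mean()), float(cc.mean()))
    frr, fcc = np.nonzero(foot_mask)
    if frr.size == 0:
        raise DetectionError("empty foot mask")
    heel_row = frr.max()
    heel_cols = fcc[frr == heel_row]
    heel_col = heel_cols[np.argmin(np.abs(heel_cols - center[1]))]
    radius = float(np.hypot(heel_row - center[0], heel_col - center[1]))
    if radius <= 0:
        raise DetectionError("degenerate heel geometry: zero removal radius")
    return ToeMaskSpec(center=center, radius_R=radius)


def remove_toes(
    foot_image: FootprintImage,
    red_range: ColorRange = RED_RANGE,
    foot_range: ColorRange = FOOT_RANGE,
) -> FootprintImage:
    """Blank everything outside the heel-anchored disk (AND with a disk mask).

    The disk is centered on the centroid of the high-pressure region with
    radius equal to the centroid-to-heel distance, so toes — which sit beyond
    the sole — fall outside and become background while the sole is kept
    unchanged (logical AND of image and mask).
    """
    foot_mask = foot_range.mask(foot_image.pixels)
    red_mask = red_range.mask(foot_image.pixels)
    spec = toe_mask_spec(foot_mask, red_mask)
    h, w = foot_image.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    disk = (
        (rows - spec.center[0]) ** 2 + (cols - spec.center[1]) ** 2
        <= spec.radius_R**2 + 1e-6  # keep the heel anchor despite float rounding
    )
    out = foot_image.pixels.copy()
    out[~disk] = BACKGROUND_RGB
    return FootprintImage(pixels=out, side=foot_image.side)


def remove_toes_grid(values: np.ndarray, high_fraction: float = 2 / 3) -> np.ndarray:
    """Grid-scale toe removal for a single-foot pressure array.

    Cells at or above ``high_fraction`` of the frame maximum play the role of
    the red (high-pressure) region; the same heel-anchored disk rule is then
    applied to the cell lattice.  Returns a copy with cells outside the disk
    zeroed.
    """
    values = np.asarray(values, dtype=float)
    if values.max() <= 0:
        raise DetectionError("empty pressure grid")
    foot_mask = values > 0
    red_mask = values >= high_fraction * values.max()
    spec = toe_mask_spec(foot_mask, red_mask)
    rows = np.arange(values.shape[0])[:, None]
    cols = np.arange(values.shape[1])[None, :]
    disk = (
        (rows - spec.center[0]) ** 2 + (cols - spec.center[1]) ** 2
        <= spec.radius_R**2 + 1e-6  # keep the heel anchor despite float rounding
    )
    out = values.copy()
    out[~disk] = 0.0
    return out


def contrast_normalize(x: np.ndarray) -> tuple[np.ndarray, Normalizer]:
    """Zero-mean unit-std normalization, x' = (x - mean) / std.

    The population standard deviation is used.  Constant input returns all
    zeros (std-0 guard).  The returned :class:`Normalizer` can re-apply the
    training statistics to held-out data.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty array")
    mean = float(x.mean())
    std = float(x.std())
    if std <= 1e-12 * max(1.0, abs(mean)):  # constant up to float rounding
        std = 0.0
    norm = Normalizer(x_mean=mean, std=std)
    return norm.apply(x), norm


def contact_mask_from_image(
    image: FootprintImage, color_range: ColorRange = FOOT_RANGE
) -> np.ndarray:
    """Foot contact mask (non-background pixels) of a processed image."""
    return color_range.mask(image.pixels)


def preprocess_frame(
    image: FootprintImage,
    foot_range: ColorRange = FOOT_RANGE,
    red_range: ColorRange = RED_RANGE,
) -> FootprintImage:
    """Full image chain: center feet, correct foot angle, remove toes.

    Toe removal runs on each image half independently so each foot gets its
    own high-pressure anchor.
    """
    centered = center_feet(image, foot_range)
    aligned = correct_rotation(centered, foot_range)
    h, w = aligned.shape
    out = aligned.pixels.copy()
    for side, cols in (("left", slice(0, w // 2)), ("right", slice(w // 2, w))):
        half = FootprintImage(pixels=aligned.pixels[:, cols].copy(), side=side)
        out[:, cols] = remove_toes(half, red_range, foot_range).pixels
    return FootprintImage(pixels=out, side=image.side)
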