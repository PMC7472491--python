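"""Synthetic plantar-pressure cohorts with analytically known arch index.

Real standing-pressure cohorts are rarely shareable, so every downstream
stage here is exercised against generated frames whose ground truth is known
by construction.  A foot is modeled as a sole silhouette on the 48x48 sensor
grid — a forefoot block, a midfoot connecting band whose medial side is
narrowed by ``midfoot_band_fraction`` (the arch-index control knob), and a
heel block — plus toe blobs separated from the sole by ``toe_gap`` rows.
High-pressure pads are placed under the metatarsal heads and the heel so the
color export contains the red band that toe removal keys on, with the pad
geometry chosen so the pad centroid sits slightly distal of the sole center
(the heel-anchored removal radius then covers the whole sole but not the
toes).

The analytic arch index of the noiseless, unjittered template is an exact
cell count using the same third-splitting rule as :mod:`plantar.arch`, which
makes it a true oracle for the preprocessing + scoring chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .arch import FIXED_THRESHOLDS, label_foot, third_boundaries
from .io import (
    GRID_SHAPE,
    CohortManifest,
    PressureGrid,
    write_manifest,
    write_pressure_grid,
)

logger = logging.getLogger(__name__)

HALF_WIDTH = GRID_SHAPE[1] // 2  # 24 columns per foot

#: pressure multiplier for the metatarsal/heel pads (renders in the red hue band)
PAD_FACTOR = 2.5
#: pressure multiplier for toe blobs (stays out of the red band)
TOE_FACTOR = 1.2


@dataclass
class SyntheticFootParams:
    """Geometry, pressure and perturbation knobs for one synthetic foot.

    Lengths and widths are in sensor cells.  ``midfoot_band_fraction`` is the
    fraction of the midfoot connecting band retained on the lateral side
    (0 = fully interrupted band, 1 = full-width band -> flat foot).
    ``noise_cv`` is the coefficient of variation of multiplicative
    (lognormal) pressure noise; jitters are per-foot pose perturbations.
    """

    foot_length: int = 30
    forefoot_width: int = 10
    heel_width: int = 7
    midfoot_band_fraction: float = 0.6
    toe_count: int = 5
    toe_gap: int = 6
    base_pressure: float = 50.0
    noise_cv: float = 0.05
    rotation_jitter: float = 3.0
    translation_jitter: int = 2
    side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4 <= self.foot_length <= GRID_SHAPE[0]):
            raise ValueError(f"foot_length must be in [4, 48], got {self.foot_length}")
        if self.forefoot_width < 1 or self.heel_width < 1:
            raise ValueError("widths must be >= 1 cell")
        if max(self.forefoot_width, self.heel_width) > HALF_WIDTH:
            raise ValueError("foot wider than one grid half")
        if not (0.0 <= self.midfoot_band_fraction <= 1.0):
            raise ValueError("midfoot_band_fraction must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.toe_count < 0 or self.toe_gap < 1:
            raise ValueError("toe_count >= 0 and toe_gap >= 1 required")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated foot."""

    analytic_ai: float
    label: str
    applied_rotation: float = 0.0
    applied_translation: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.analytic_ai <= 1.0):
            raise ValueError("analytic_ai must lie in [0, 1]")


def _row_width(params: SyntheticFootParams, r: int) -> int:
    """Silhouette width at sole row ``r`` (0 = forefoot tip), before the arch cut."""
    L = params.foot_length
    b1, b2 = third_boundaries(L)
    if r < b1:  # forefoot, rounded tip
        w = params.forefoot_width
        if r == 0:
            w -= 4
        elif r == 1:
            w -= 2
        return max(3, w)
    if r < b2:  # midfoot: taper forefoot -> heel width
        span = max(b2 - b1 - 1, 1)
        t = (r - b1) / span
        return max(3, int(round(params.forefoot_width + t * (params.heel_width - params.forefoot_width))))
    w = params.heel_width  # hindfoot, rounded heel
    if r == L - 1:
        w -= 4
    elif r == L - 2:
        w -= 2
    return max(3, w)


def _sole_template(params: SyntheticFootParams, width: int) -> np.ndarray:
    """Boolean sole mask (canonical right foot: medial edge on the left)."""
    L = params.foot_length
    b1, b2 = third_boundaries(L)
    sole = np.zeros((L, width), dtype=bool)
    for r in range(L):
        w = _row_width(params, r)
        start = (width - w) // 2
        if b1 <= r < b2:
            keep = int(round(params.midfoot_band_fraction * w))
            # retain the lateral-most columns (right side of a right foot)
            sole[r, start + (w - keep): start + w] = True
        else:
            sole[r, start: start + w] = True
    return sole


def _toe_template(params: SyntheticFootParams, width: int) -> np.ndarray:
    """Boolean toe mask, 2 rows tall, aligned with the forefoot span."""
    toes = np.zeros((2, width), dtype=bool)
    n = params.toe_count
    if n == 0:
        return toes
    w = max(3, params.forefoot_width)
    start = (width - w) // 2
    # big toe (2 cols) on the medial side, remaining toes 1 col each
    centers = np.linspace(start + 1, start + w - 1, n).round().astype(int)
    toes[:, centers[0] - 1: centers[0] + 1] = True
    for c in centers[1:]:
        toes[1, c] = True  # lesser toes slightly shorter
        toes[0, c] = params.toe_count <= 3  # only when few, make them long
    return toes


def _pressure_template(params: SyntheticFootParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pressure, sole_mask, toe_mask) arrays for the unjittered template.

    Layout rows: [toes (2)] [gap] [sole (foot_length)].
    """
    L = params.foot_length
    width = max(params.forefoot_width, params.heel_width)
    sole = _sole_template(params, width)
    toes = _toe_template(params, width)
    height = 2 + params.toe_gap + L
    pressure = np.zeros((height, width), dtype=float)
    sole_mask = np.zeros((height, width), dtype=bool)
    toe_mask = np.zeros((height, width), dtype=bool)
    toe_mask[:2] = toes
    sole_mask[2 + params.toe_gap:] = sole
    pressure[toe_mask] = params.base_pressure * TOE_FACTOR
    pressure[sole_mask] = params.base_pressure

    # High-pressure pads under the metatarsal heads and the heel.  Toe
    # removal keeps a disk of radius R = |pad centroid -> heel end| around
    # the pad centroid, so the centroid row c (in sole coordinates) must
    # satisfy  (heel_end + toe_row)/2 < c <= (heel_end + tip)/2:  distal
    # enough that the disk covers the forefoot tip, proximal enough that it
    # excludes the toes.  The metatarsal pad is fixed; the heel pad's upper
    # edge is chosen so the combined centroid lands at the window center.
    off = 2 + params.toe_gap
    met_rows = np.arange(int(round(0.06 * L)), max(int(round(0.20 * L)), int(round(0.06 * L)) + 2))
    target_c = (L - 1) / 2.0 - (params.toe_gap + 2) / 4.0
    heel_hi = int(round(0.92 * L))
    best_h0, best_err = heel_hi - 2, np.inf
    n_met = sum(int(sole_mask[off + r].sum()) for r in met_rows)
    c_met = (
        sum(r * int(sole_mask[off + r].sum()) for r in met_rows) / max(n_met, 1)
    )
    for h0 in range(heel_hi - 2, int(round(0.55 * L)), -1):
        heel_rows = np.arange(h0, heel_hi)
        n_heel = sum(int(sole_mask[off + r].sum()) for r in heel_rows)
        if n_heel == 0:
            continue
        c_heel = sum(r * int(sole_mask[off + r].sum()) for r in heel_rows) / n_heel
        c = (n_met * c_met + n_heel * c_heel) / (n_met + n_heel)
        if abs(c - target_c) < best_err:
            best_err, best_h0 = abs(c - target_c), h0
    for band in (
        slice(off + int(met_rows[0]), off + int(met_rows[-1]) + 1),
        slice(off + best_h0, off + heel_hi),
    ):
        region = sole_mask[band]
        pressure[band][region] = params.base_pressure * PAD_FACTOR
    return pressure, sole_mask, toe_mask


def analytic_ai(params: SyntheticFootParams) -> float:
    """Exact arch index of the noiseless, unjittered sole template.

    Counts middle-third contact cells over total sole cells (toes excluded)
    with the same band rule used by :func:`plantar.arch.segment_thirds`.
    """
    _, sole_mask, _ = _pressure_template(params)
    rows = np.flatnonzero(sole_mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("degenerate template: zero sole contact area")
    top, bottom = int(rows[0]), int(rows[-1])
    b1, b2 = third_boundaries(bottom - top + 1)
    B = int(sole_mask[top + b1: top + b2].sum())
    total = int(sole_mask.sum())
    return B / total


def band_fraction_for_ai(target_ai: float, params: SyntheticFootParams) -> float:
    """Invert the AI <- midfoot_band_fraction map by monotone bisection.

    The map is a step function (integer cell counts), so the returned
    fraction reproduces ``target_ai`` only to the template's quantization;
    the caller should re-read :func:`analytic_ai` for the realized value.
    """
    lo, hi = 0.0, 1.0
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if analytic_ai(replace(params, midfoot_band_fraction=mid)) < target_ai:
            lo = mid
        else:
            hi = mid
    # pick whichever bracket end lands closer to the target
    cands = [lo, hi, 0.5 * (lo + hi)]
    errs = [abs(analytic_ai(replace(params, midfoot_band_fraction=f)) - target_ai) for f in cands]
    return cands[int(np.argmin(errs))]


def generate_foot(params: SyntheticFootParams) -> tuple[PressureGrid, SyntheticTruth]:
    """Generate one single-foot 48x48 frame plus its ground truth.

    The foot is placed in the grid half matching ``params.side``; the same
    seed produces horizontally mirrored frames for the two sides.  Pose
    jitter exceeding the half-grid bounds is clamped with a logged warning.
    """
    rng = np.random.default_rng(params.seed)
    pressure, sole_mask, toe_mask = _pressure_template(params)
    truth_ai = analytic_ai(params)

    # canonical right-foot half block (48 rows x 24 cols), template centered
    block = np.zeros((GRID_SHAPE[0], HALF_WIDTH), dtype=float)
    th, tw = pressure.shape
    r0 = (GRID_SHAPE[0] - th) // 2
    c0 = (HALF_WIDTH - tw) // 2
    block[r0: r0 + th, c0: c0 + tw] = pressure

    rot = float(rng.uniform(-params.rotation_jitter, params.rotation_jitter))
    if abs(rot) > 1e-9:
        rotated = ndimage.rotate(block, rot, reshape=False, order=0, cval=0.0)
        if rotated[0].any() or rotated[-1].any() or rotated[:, 0].any() or rotated[:, -1].any():
            logger.warning("rotation jitter %.1f deg clipped the template; halving", rot)
            rot *= 0.5
            rotated = ndimage.rotate(block, rot, reshape=False, order=0, cval=0.0)
        block = rotated

    tj = params.translation_jitter
    dr = int(rng.integers(-tj, tj + 1)) if tj > 0 else 0
    dc = int(rng.integers(-tj, tj + 1)) if tj > 0 else 0
    occ_r = np.flatnonzero(block.any(axis=1))
    occ_c = np.flatnonzero(block.any(axis=0))
    dr_ok = int(np.clip(dr, -occ_r[0], GRID_SHAPE[0] - 1 - occ_r[-1]))
    dc_ok = int(np.clip(dc, -occ_c[0], HALF_WIDTH - 1 - occ_c[-1]))
    if (dr_ok, dc_ok) != (dr, dc):
        logger.warning("translation jitter (%d, %d) clamped to (%d, %d)", dr, dc, dr_ok, dc_ok)
    dr, dc = dr_ok, dc_ok
    block = np.roll(np.roll(block, dr, axis=0), dc, axis=1)

    if params.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=block.shape)
        block = block * np.where(block > 0, factors, 1.0)

    frame = np.zeros(GRID_SHAPE, dtype=float)
    frame[:, HALF_WIDTH:] = block
    if params.side == "left":
        frame = frame[:, ::-1]
        rot, dc = -rot, -dc

    grid = PressureGrid(values=frame, frame_id=f"synthetic_{params.side}_{params.seed}")
    truth = SyntheticTruth(
        analytic_ai=truth_ai,
        label=label_foot(truth_ai, FIXED_THRESHOLDS),
        applied_rotation=rot,
        applied_translation=(dr, dc),
    )
    return grid, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: per-class target-AI bands.  Margins to the 0.17 / 0.28 cut-offs exceed
#: both the template's AI quantization and the grid-scale AI measurement
#: error (<= 0.02), so classes are well separated: neither rasterization nor
#: multiplicative noise can push a foot's measured AI across a cut-off.
CLASS_AI_BANDS = {
    "concave": (0.06, 0.135),
    "normal": (0.205, 0.245),
    "flat": (0.315, 0.365),
}

#: within-subject left/right target-AI standard deviation (feet of one person
#: share a deformation type with small asymmetry)
WITHIN_SUBJECT_AI_SD = 0.008


@dataclass
class SyntheticFoot:
    subject_id: str
    side: str
    grid: PressureGrid
    truth: SyntheticTruth
    params: SyntheticFootParams


@dataclass
class SyntheticCohort:
    feet: list[SyntheticFoot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.feet)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.feet:
            seen.setdefault(f.subject_id, None)
        return list(seen)

    def by_side(self, side: str) -> list[SyntheticFoot]:
        return [f for f in self.feet if f.side == side]


def largest_remainder_counts(n: int, proportions) -> list[int]:
    """Apportion ``n`` items to proportions, largest-remainder rounding."""
    p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    raw = n * p
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts.tolist()


def generate_cohort(
    n_subjects: int,
    class_mix=(1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    base_params: SyntheticFootParams | None = None,
) -> SyntheticCohort:
    """Generate a cohort of paired left/right feet with known labels.

    Both feet of a subject are drawn from the same foot-type class with a
    small within-subject AI offset.  Per-subject foot dimensions vary so the
    realized AI values spread within each class band.  Class subject counts
    follow ``class_mix`` by largest-remainder rounding.
    """
    if n_subjects <= 0:
        raise ValueError(f"n_subjects must be positive, got {n_subjects}")
    base = base_params or SyntheticFootParams()
    counts = largest_remainder_counts(n_subjects, class_mix)
    classes = [lbl for lbl, c in zip(("concave", "normal", "flat"), counts) for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(classes)

    cohort = SyntheticCohort()
    for i, cls in enumerate(classes):
        sid = f"S{i:03d}"
        lo, hi = CLASS_AI_BANDS[cls]
        target = float(rng.uniform(lo, hi))
        dims = replace(
            base,
            foot_length=int(rng.integers(28, 35)),
            forefoot_width=int(rng.integers(9, 13)),
            heel_width=int(rng.integers(6, 9)),
        )
        for side in ("left", "right"):
            t = target if side == "left" else float(
                np.clip(target + rng.normal(0.0, WITHIN_SUBJECT_AI_SD), lo, hi)
            )
            frac = band_fraction_for_ai(t, replace(dims, side=side))
            params = replace(
                dims,
                side=side,
                midfoot_band_fraction=frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            # step the band fraction if quantization pushed the truth label
            # out of the intended class
            for _ in range(8):
                if label_foot(analytic_ai(params), FIXED_THRESHOLDS) == cls:
                    break
                ai_now = analytic_ai(params)
                step = 0.05 if ai_now < (lo + hi) / 2 else -0.05
                params = replace(
                    params,
                    midfoot_band_fraction=float(
                        np.clip(params.midfoot_band_fraction + step, 0.0, 1.0)
                    ),
                )
            else:
                warnings.warn(f"subject {sid}: could not realize class {cls!r}")
            grid, truth = generate_foot(params)
            grid.frame_id = f"{sid}_{side}"
            cohort.feet.append(SyntheticFoot(sid, side, grid, truth, params))
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write grids, a YAML manifest and a truth CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grids_dir = out_dir / "grids"
    grids_dir.mkdir(exist_ok=True)
    entries = []
    by_subject: dict[str, dict[str, SyntheticFoot]] = {}
    for foot in cohort.feet:
        by_subject.setdefault(foot.subject_id, {})[foot.side] = foot
    truth_rows = ["subject_id,side,analytic_ai,label,applied_rotation_deg"]
    for sid, sides in by_subject.items():
        paths = {}
        for side in ("left", "right"):
            foot = sides[side]
            p = grids_dir / f"{sid}_{side}.csv"
            write_pressure_grid(foot.grid, p)
            paths[side] = p
            truth_rows.append(
                f"{sid},{side},{foot.truth.analytic_ai:.6f},{foot.truth.label},"
                f"{foot.truth.applied_rotation:.3f}"
            )
        entries.append((sid, paths["left"], paths["right"]))
    manifest = CohortManifest(entries=entries, provenance="plantar synthetic cohort")
    manifest_path = write_manifest(manifest, out_dir / "manifest.yaml")
    (out_dir / "truth.csv").write_text("\n".join(truth_rows) + "\n")
    return manifest_path
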