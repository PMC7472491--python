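"""Arch index scoring and foot-type labeling.

The arch index (AI) of a toe-less footprint is the fraction of contact area
falling in the midfoot:  AI = B / (A + B + C), where A, B, C are the contact
areas of the forefoot, midfoot and hindfoot obtained by dividing the foot
axis (heel end to forefoot tip, toes excluded) into three equal-length bands.

Low AI means a high medial longitudinal arch (concave foot / pes cavus);
high AI means a collapsed arch (flat foot / pes planus).  Cohort cut-offs can
be fit either as mean +/- one standard deviation or as the first and third
quartiles; the fixed cut-offs (0.17, 0.28) reported for adult cohorts are
provided as :data:`FIXED_THRESHOLDS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical adult cut-offs: concave < 0.17, 0.17 <= normal <= 0.28, flat > 0.28
FIXED_LOW = 0.17
FIXED_HIGH = 0.28

LABELS = ("concave", "normal", "flat")


@dataclass
class ArchSegmentation:
    """Per-band contact areas of a toe-less footprint.

    ``area_A``/``area_B``/``area_C`` are contact-cell counts for the forefoot
    (distal third), midfoot and hindfoot bands.  ``band_rows`` records the
    half-open row intervals actually used, top row first (the footprint is
    assumed oriented toes-up), so downstream feature extraction can reuse the
    identical bands.
    """

    area_A: int
    area_B: int
    area_C: int
    axis_length: int
    band_rows: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if min(self.area_A, self.area_B, self.area_C) < 0:
            raise ValueError("band areas must be non-negative")
        if self.area_A + self.area_B + self.area_C <= 0:
            raise ValueError("footprint has zero total contact area")

    @property
    def total_area(self) -> int:
        return self.area_A + self.area_B + self.area_C


@dataclass
class ArchIndexScore:
    ai: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ai <= 1.0):
            raise ValueError(f"arch index must lie in [0, 1], got {self.ai}")


@dataclass
class ThresholdFit:
    """Foot-type cut-offs with the fit statistics retained for reporting."""

    method: str  # mu_sigma | quartile | fixed
    low: float
    high: float
    mu: float = float("nan")
    sigma: float = float("nan")
    q1: float = float("nan")
    q3: float = float("nan")

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low cut-off {self.low} exceeds high {self.high}")


FIXED_THRESHOLDS = ThresholdFit(method="fixed", low=FIXED_LOW, high=FIXED_HIGH)


def third_boundaries(axis_length: int) -> tuple[int, int]:
    """Row offsets (from the distal end) splitting an axis into three bands.

    Boundaries fall at round(L/3) and round(2L/3); for lengths not divisible
    by three the band lengths differ by at most one cell.
    """
    if axis_length <= 0:
        raise ValueError("axis length must be positive")
    b1 = int(np.floor(axis_length / 3 + 0.5))
    b2 = int(np.floor(2 * axis_length / 3 + 0.5))
    return b1, b2


def _as_contact_mask(footprint, contact_threshold: float) -> np.ndarray:
    # accepts a PressureGrid, a float array, or a boolean mask
    values = getattr(footprint, "values", footprint)
    values = np.asarray(values)
    if values.dtype == bool:
        return values
    return values > contact_threshold


def segment_thirds(footprint, contact_threshold: float = 0.0) -> ArchSegmentation:
    """Split a toe-less footprint into forefoot/midfoot/hindfoot contact areas.

    ``footprint`` may be a PressureGrid, a 2-D pressure array, or a boolean
    contact mask, oriented toes-up.  Contact means pressure strictly above
    ``contact_threshold`` (kPa).  The foot axis length is the row span of the
    contact region; areas are contact-cell counts per band.
    """
    mask = _as_contact_mask(footprint, contact_threshold)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("empty contact region: nothing to segment")
    top, bottom = int(rows[0]), int(rows[-1])
    axis_length = bottom - top + 1
    b1, b2 = third_boundaries(axis_length)
    bands = (
        (top, top + b1),
        (top + b1, top + b2),
        (top + b2, bottom + 1),
    )
    areas = [int(mask[lo:hi].sum()) for lo, hi in bands]
    return ArchSegmentation(
        area_A=areas[0],
        area_B=areas[1],
        area_C=areas[2],
        axis_length=axis_length,
        band_rows=bands,
    )


def compute_ai(seg: ArchSegmentation) -> ArchIndexScore:
    """Arch index AI = B / (A + B + C) from band contact areas."""
    total = seg.total_area
    if total <= 0:
        raise ValueError("zero total contact area")
    return ArchIndexScore(ai=seg.area_B / total)


def fit_thresholds(ai_values, method: str = "mu_sigma") -> ThresholdFit:
    """Fit concave/normal/flat cut-offs from a cohort of AI values.

    ``mu_sigma`` uses mean +/- one (population) standard deviation;
    ``quartile`` uses Q1 and Q3.  Both sets of statistics are stored on the
    fit regardless of method.
    """
    values = np.asarray(list(ai_values), dtype=float)
    if method == "mu_sigma":
        if values.size < 2:
            raise ValueError("mu_sigma fit needs at least 2 AI values")
    elif method == "quartile":
        if values.size < 4:
            raise ValueError("quartile fit needs at least 4 AI values")
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mu = float(values.mean())
    sigma = float(values.std())
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant cohort up to rounding
        sigma = 0.0
    q1 = float(np.percentile(values, 25))
    q3 = float(np.percentile(values, 75))
    if method == "mu_sigma":
        low, high = mu - sigma, mu + sigma
    else:
        low, high = q1, q3
    return ThresholdFit(method=method, low=low, high=high, mu=mu, sigma=sigma, q1=q1, q3=q3)


def label_foot(score: ArchIndexScore | float, fit: ThresholdFit = FIXED_THRESHOLDS) -> str:
    """Assign concave / normal / flat; boundary values are labeled normal."""
    ai = score.ai if isinstance(score, ArchIndexScore) else float(score)
    if ai < fit.low:
        return "concave"
    if ai > fit.high:
        return "flat"
    return "normal"
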