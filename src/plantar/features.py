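"""Numeric plantar features and Pearson-correlation feature selection.

Fourteen per-foot scalars spanning three categories used in plantar-pressure
analysis: pressure statistics, contact-area parameters (on the same
forefoot/midfoot/hindfoot bands as the arch index), and foot-shape
parameters.  Cohort-level selection keeps the features whose absolute
Pearson correlation with the arch index meets a threshold (default 0.2),
reported in descending |r|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arch import ArchSegmentation

FEATURE_NAMES = (
    # pressure statistics (kPa-based)
    "sum_pressure",
    "mean_pressure",
    "max_pressure",
    "std_pressure",
    # contact-area parameters (cells)
    "foot_area",
    "forefoot_area",
    "midfoot_area",
    "hindfoot_area",
    # regional pressure ratios (dimensionless, sum to 1)
    "front_pressure_ratio",
    "mid_pressure_ratio",
    "rear_pressure_ratio",
    # foot-shape parameters
    "foot_length",
    "foot_width",
    "length_width_ratio",
)

#: default |r| cut-off for keeping a feature
SELECTION_THRESHOLD = 0.2


@dataclass
class FeatureVector:
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector missing {sorted(missing)}")

    def as_array(self, names=FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class FeatureSelection:
    correlations: dict[str, float]
    threshold: float
    selected: list[str] = field(default_factory=list)


def extract_features(grid, seg: ArchSegmentation, contact_threshold: float = 0.0) -> FeatureVector:
    """Extract the 14-feature vector from a toe-less pressure array.

    ``grid`` is a PressureGrid or 2-D pressure array whose toes are already
    removed; ``seg`` must come from :func:`plantar.arch.segment_thirds` on
    the same array so the regional ratios use identical bands.
    """
    values = np.asarray(getattr(grid, "values", grid), dtype=float)
    mask = values > contact_threshold
    if not mask.any():
        raise ValueError("empty footprint: no contact cells")
    if seg.band_rows is None:
        raise ValueError("segmentation lacks band rows; recompute with segment_thirds")
    contact = values[mask]
    total_pressure = float(contact.sum())
    band_pressure = [float(values[lo:hi][mask[lo:hi]].sum()) for lo, hi in seg.band_rows]
    cols = np.flatnonzero(mask.any(axis=0))
    width = int(cols[-1] - cols[0] + 1)
    feats = {
        "sum_pressure": total_pressure,
        "mean_pressure": float(contact.mean()),
        "max_pressure": float(contact.max()),
        "std_pressure": float(contact.std()),
        "foot_area": float(mask.sum()),
        "forefoot_area": float(seg.area_A),
        "midfoot_area": float(seg.area_B),
        "hindfoot_area": float(seg.area_C),
        "front_pressure_ratio": band_pressure[0] / total_pressure,
        "mid_pressure_ratio": band_pressure[1] / total_pressure,
        "rear_pressure_ratio": band_pressure[2] / total_pressure,
        "foot_length": float(seg.axis_length),
        "foot_width": float(width),
        "length_width_ratio": seg.axis_length / width,
    }
    return FeatureVector(values=feats)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a cohort table (rows = feet)."""
    return pd.DataFrame([v.values for v in vectors], columns=list(FEATURE_NAMES))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance input; Pearson r recorded as 0")
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def select_features(
    matrix: pd.DataFrame,
    ai_values,
    threshold: float = SELECTION_THRESHOLD,
) -> FeatureSelection:
    """Keep features with |Pearson r| >= threshold against the arch index.

    Correlations are reported for every feature, ordered by descending |r|;
    zero-variance features get r = 0 with a warning rather than an error.
    """
    ai = np.asarray(list(ai_values), dtype=float)
    if len(matrix) != ai.size:
        raise ValueError("feature table and AI values are misaligned")
    if ai.size < 3:
        raise ValueError("need at least 3 samples to correlate")
    corr = {c: pearson_r(matrix[c].to_numpy(), ai) for c in matrix.columns}
    ordered = sorted(corr, key=lambda c: -abs(corr[c]))
    selected = [c for c in ordered if abs(corr[c]) >= threshold]
    return FeatureSelection(
        correlations={c: corr[c] for c in ordered},
        threshold=threshold,
        selected=selected,
    )
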