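"""Left/right cross-pairing augmentation and paired-dataset splitting.

A cohort of n subjects yields 2n labeled single-foot records; pairing every
left record with every right record multiplies the dataset to (2n/2)^2 pairs
— 96 subjects give 192 single-foot records and 36,864 (192 x 192) pairs —
each labeled with one of the nine ordered (left class, right class)
subclasses.

The faithful split mode stratifies pairs by subclass without regard to which
physical subjects contributed, which lets a subject appear on both sides of
the train/test divide; a leakage-safe grouped mode that splits by subject is
provided as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .arch import LABELS

logger = logging.getLogger(__name__)

SUBCLASSES = tuple(f"{l}|{r}" for l in LABELS for r in LABELS)


@dataclass
class FootRecord:
    """One labeled single-foot sample."""

    subject_id: str
    side: str
    grid: object  # PressureGrid
    ai: float
    label: str
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class PairedSample:
    left_index: int
    right_index: int
    subclass: str
    subjects: frozenset

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        if len(self.subjects) not in (1, 2):
            raise ValueError("a pair involves one or two subjects")


def mirror_record(record: FootRecord) -> FootRecord:
    """Horizontally mirror a foot record so it can serve as the other side.

    The pressure frame is flipped left-for-right; arch index, label and
    numeric features are chirality-invariant and carried over unchanged.
    """
    from .io import PressureGrid

    flipped = PressureGrid(
        values=record.grid.values[:, ::-1],
        sensor_pitch=record.grid.sensor_pitch,
        frame_id=record.grid.frame_id + "_mirrored",
    )
    return FootRecord(
        subject_id=record.subject_id,
        side="left" if record.side == "right" else "right",
        grid=flipped,
        ai=record.ai,
        label=record.label,
        features=None if record.features is None else record.features.copy(),
    )


def augment_sides(
    lefts: list[FootRecord], rights: list[FootRecord]
) -> tuple[list[FootRecord], list[FootRecord]]:
    """Double each side by mirroring the other side's records.

    n subjects give n left + n right originals; switching both feet yields
    2n records per side (96 subjects -> 192 left and 192 right records).
    """
    return (
        list(lefts) + [mirror_record(r) for r in rights],
        list(rights) + [mirror_record(r) for r in lefts],
    )


def pair_feet(lefts: list[FootRecord], rights: list[FootRecord]) -> list[PairedSample]:
    """Full cross product of left and right records, left index major.

    Every pair carries the ordered subclass (left label | right label) and
    the set of contributing subject ids (self-pairs — both feet from the
    same subject — are kept).
    """
    for rec in (*lefts, *rights):
        if rec.label is None:
            raise ValueError(f"record {rec.subject_id}/{rec.side} is unlabeled")
    for side, recs in (("left", lefts), ("right", rights)):
        for rec in recs:
            if rec.side != side:
                raise ValueError(f"record {rec.subject_id} listed under wrong side")
    pairs = []
    for i, left in enumerate(lefts):
        for j, right in enumerate(rights):
            pairs.append(
                PairedSample(
                    left_index=i,
                    right_index=j,
                    subclass=f"{left.label}|{right.label}",
                    subjects=frozenset({left.subject_id, right.subject_id}),
                )
            )
    return pairs


def compose_pair_grid(left: FootRecord, right: FootRecord) -> np.ndarray:
    """Both-feet pressure frame for a pair (left and right halves side by side)."""
    half = left.grid.values.shape[1] // 2
    out = np.zeros_like(left.grid.values)
    out[:, :half] = left.grid.values[:, :half]
    out[:, half:] = right.grid.values[:, half:]
    return out


def pair_features(left: FootRecord, right: FootRecord) -> np.ndarray:
    """Numeric-branch input for a pair: concatenated left and right features."""
    if left.features is None or right.features is None:
        raise ValueError("records lack extracted features")
    return np.concatenate([left.features, right.features])


def group_aware_split(
    pairs: list[PairedSample],
    test_fraction: float = 0.2,
    mode: str = "paper",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split pair indices into train and test sets.

    ``mode='paper'`` stratifies by subclass only (subjects may leak across
    the split, which is logged); ``mode='grouped'`` assigns whole subjects
    to one side so no subject contributes pairs to both.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(pairs)
    indices = np.arange(n)
    subclasses = np.array([p.subclass for p in pairs])
    if mode == "paper":
        logger.warning(
            "mode='paper' stratifies by subclass only; pairs sharing a subject "
            "can appear in both train and test"
        )
        # merge subclasses too small to stratify into a catch-all stratum
        counts = {s: int((subclasses == s).sum()) for s in set(subclasses)}
        small = {s for s, c in counts.items() if c < 2}
        strata = np.where(np.isin(subclasses, sorted(small)), "__rare__", subclasses)
        if small:
            logger.warning("subclasses too small to stratify, merged: %s", sorted(small))
        train, test = train_test_split(
            indices, test_size=test_fraction, stratify=strata, random_state=seed
        )
        return np.sort(train), np.sort(test)
    if mode == "grouped":
        subjects = sorted({s for p in pairs for s in p.subjects})
        rng = np.random.default_rng(seed)
        shuffled = np.array(subjects)
        rng.shuffle(shuffled)
        n_test = max(1, int(round(test_fraction * len(shuffled))))
        test_subjects = set(shuffled[:n_test])
        test_mask = np.array([p.subjects <= test_subjects for p in pairs])
        train_mask = np.array([p.subjects.isdisjoint(test_subjects) for p in pairs])
        # pairs straddling the subject split are dropped from both sides
        return indices[train_mask], indices[test_mask]
    raise ValueError(f"unknown split mode {mode!r}")


def stratified_subsample(
    pairs: list[PairedSample], n_keep: int, seed: int = 0
) -> np.ndarray:
    """Subclass-stratified subsample of pair indices (largest-remainder sizes)."""
    from .synthetic import largest_remainder_counts

    if n_keep >= len(pairs):
        return np.arange(len(pairs))
    subclasses = np.array([p.subclass for p in pairs])
    present = sorted(set(subclasses))
    props = np.array([(subclasses == s).sum() / len(pairs) for s in present])
    counts = largest_remainder_counts(n_keep, props)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for s, c in zip(present, counts):
        idx = np.flatnonzero(subclasses == s)
        keep.append(rng.choice(idx, size=min(c, idx.size), replace=False))
    return np.sort(np.concatenate(keep))
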