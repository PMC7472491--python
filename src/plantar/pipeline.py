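"""End-to-end orchestration: cohort -> records -> pairs -> models -> reports.

The numeric route works at sensor-grid scale (toe removal on the cell
lattice, band segmentation, arch-index scoring, 14-feature extraction); the
image route composes both-feet frames for the image classifier.  The
benchmark runner wires the whole chain — labeling, Pearson feature
selection, full left/right cross-pairing, a stratified subsample for
tractable model fitting, and stratified-CV evaluation of the k-NN, CART and
image branches plus the stacking ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arch import FIXED_THRESHOLDS, ThresholdFit, compute_ai, label_foot, segment_thirds
from .classifiers import (
    CartClassifier,
    CartConfig,
    ImageClassifier,
    KnnConfig,
    KNNClassifier,
    finetune_preset,
)
from .ensemble import CvReport, MetaNetConfig, StackingEnsemble, evaluate_cv
from .features import extract_features, feature_table, select_features
from .pairing import (
    FootRecord,
    augment_sides,
    compose_pair_grid,
    pair_feet,
    stratified_subsample,
)
from .preprocess import Normalizer, remove_toes_grid
from .synthetic import SyntheticCohort, generate_cohort


def build_record(subject_id: str, side: str, grid, thresholds: ThresholdFit = FIXED_THRESHOLDS) -> FootRecord:
    """Score one single-foot grid: toe removal, segmentation, AI, label, features."""
    toeless = remove_toes_grid(grid.values)
    seg = segment_thirds(toeless)
    score = compute_ai(seg)
    vec = extract_features(toeless, seg)
    return FootRecord(
        subject_id=subject_id,
        side=side,
        grid=grid,
        ai=score.ai,
        label=label_foot(score, thresholds),
        features=vec.as_array(),
    )


def records_from_cohort(
    cohort: SyntheticCohort, thresholds: ThresholdFit = FIXED_THRESHOLDS
) -> tuple[list[FootRecord], list[FootRecord]]:
    """Score every foot of a cohort; returns (lefts, rights) in subject order."""
    lefts, rights = [], []
    for foot in cohort.feet:
        rec = build_record(foot.subject_id, foot.side, foot.grid, thresholds)
        (lefts if foot.side == "left" else rights).append(rec)
    return lefts, rights


class _NormalizedKnn:
    """k-NN behind per-feature contrast normalization fit on the training set."""

    def __init__(self, k: int = 7):
        self.k = k

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        self.norms_ = [Normalizer(x_mean=c.mean(), std=c.std()) for c in x.T]
        self.model_ = KNNClassifier(KnnConfig(k=min(self.k, x.shape[0]))).fit(
            self._apply(x), y
        )
        self.classes_ = self.model_.classes_
        return self

    def _apply(self, x):
        x = np.asarray(x, dtype=float)
        return np.column_stack([n.apply(c) for n, c in zip(self.norms_, x.T)])

    def predict(self, x):
        return self.model_.predict(self._apply(x))

    def predict_proba(self, x):
        return self.model_.predict_proba(self._apply(x))


class _NormalizedCart:
    def __init__(self, max_depth: int = 9):
        self.max_depth = max_depth

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        self.norms_ = [Normalizer(x_mean=c.mean(), std=c.std()) for c in x.T]
        self.model_ = CartClassifier(CartConfig(max_depth=self.max_depth)).fit(
            self._apply(x), y
        )
        self.classes_ = self.model_.classes_
        return self

    def _apply(self, x):
        x = np.asarray(x, dtype=float)
        return np.column_stack([n.apply(c) for n, c in zip(self.norms_, x.T)])

    def predict(self, x):
        return self.model_.predict(self._apply(x))

    def predict_proba(self, x):
        return self.model_.predict_proba(self._apply(x))


@dataclass
class BenchmarkData:
    """Materialized pair dataset for model fitting."""

    pair_count: int
    subclasses: np.ndarray  # per kept pair
    features: np.ndarray  # kept pairs x (2 * n_selected features)
    images: np.ndarray  # kept pairs x 48 x 48 both-feet grids
    selected_features: list[str]
    correlations: dict[str, float]
    n_subclasses_total: int
    ai_values: np.ndarray = field(default=None)


def prepare_from_records(
    lefts: list[FootRecord],
    rights: list[FootRecord],
    seed: int = 0,
    n_pairs_kept: int = 720,
    n_main_features: int = 5,
) -> BenchmarkData:
    """Materialize the paired dataset from scored single-foot records.

    Sides are first doubled by the mirror-switch augmentation (n subjects ->
    2n records per side), then fully cross-paired; the full pair set is
    built and counted, and a subclass-stratified subsample of
    ``n_pairs_kept`` pairs is materialized for model fitting.  Per-foot
    feature vectors are reduced to the ``n_main_features`` top
    Pearson-selected features before concatenating left and right.
    """
    all_records = lefts + rights
    toeless = [remove_toes_grid(r.grid.values) for r in all_records]
    table = feature_table(
        [extract_features(t, segment_thirds(t)) for t in toeless]
    )
    ai_values = np.array([r.ai for r in all_records])
    selection = select_features(table, ai_values)
    main = selection.selected[:n_main_features]
    sel_idx = [list(table.columns).index(c) for c in main]

    lefts, rights = augment_sides(lefts, rights)
    pairs = pair_feet(lefts, rights)
    keep = stratified_subsample(pairs, n_pairs_kept, seed=seed)
    subclasses = np.array([pairs[i].subclass for i in keep])
    feats = np.array([
        np.concatenate([
            lefts[pairs[i].left_index].features[sel_idx],
            rights[pairs[i].right_index].features[sel_idx],
        ])
        for i in keep
    ])
    images = np.array([
        compose_pair_grid(lefts[pairs[i].left_index], rights[pairs[i].right_index])
        for i in keep
    ])
    return BenchmarkData(
        pair_count=len(pairs),
        subclasses=subclasses,
        features=feats,
        images=images,
        selected_features=main,
        correlations=selection.correlations,
        n_subclasses_total=len({p.subclass for p in pairs}),
        ai_values=ai_values,
    )


def prepare_benchmark(
    n_subjects: int = 96,
    class_mix=(1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    n_pairs_kept: int = 720,
    thresholds: ThresholdFit = FIXED_THRESHOLDS,
    n_main_features: int = 5,
) -> BenchmarkData:
    """Generate a synthetic cohort and materialize its paired dataset."""
    cohort = generate_cohort(n_subjects, class_mix=class_mix, seed=seed)
    lefts, rights = records_from_cohort(cohort, thresholds)
    return prepare_from_records(
        lefts, rights, seed=seed, n_pairs_kept=n_pairs_kept,
        n_main_features=n_main_features,
    )


def run_benchmark(
    data: BenchmarkData,
    models=("knn", "cart", "cnn", "stacking"),
    seed: int = 0,
    k_folds: int = 5,
    test_fraction: float = 0.2,
    cnn_epochs: int = 20,
    meta_epochs: int = 60,
) -> dict[str, CvReport]:
    """Evaluate each requested model with the stratified 80/20 + k-fold protocol."""
    y = data.subclasses
    reports: dict[str, CvReport] = {}

    def knn_factory():
        return _NormalizedKnn(k=7)

    def cart_factory():
        return _NormalizedCart(max_depth=9)

    def cnn_factory():
        cfg = finetune_preset("tiny_test", n_classes=len(np.unique(y)),
                              epochs=cnn_epochs, seed=seed)
        return ImageClassifier(cfg)

    simple = {
        "knn": (knn_factory, data.features),
        "cart": (cart_factory, data.features),
        "cnn": (cnn_factory, data.images),
    }
    for name in models:
        if name == "stacking":
            continue
        factory, x = simple[name]

        def fit_predict(tr, te, factory=factory, x=x):
            return factory().fit(x[tr], y[tr]).predict(x[te])

        reports[name] = evaluate_cv(
            fit_predict, y, k_folds=k_folds, test_fraction=test_fraction, seed=seed
        )

    if "stacking" in models:
        meta_cfg = MetaNetConfig(epochs=meta_epochs)

        def fit_predict(tr, te):
            ens = StackingEnsemble(
                base_factories={"knn": knn_factory, "cnn": cnn_factory},
                inputs={"knn": data.features, "cnn": data.images},
                n_folds=k_folds,
                meta_config=meta_cfg,
                seed=seed,
            ).fit(tr, y[tr])
            return ens.predict(te)

        reports["stacking"] = evaluate_cv(
            fit_predict, y, k_folds=k_folds, test_fraction=test_fraction, seed=seed
        )
    return reports


def reports_to_frame(reports: dict[str, CvReport]) -> pd.DataFrame:
    """Statistics table, one column per model (mean/std/min/median/max rows)."""
    rows = ("mean", "std", "min", "median", "max")
    return pd.DataFrame(
        {name: [getattr(r, s) for s in rows] for name, r in reports.items()},
        index=rows,
    )
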