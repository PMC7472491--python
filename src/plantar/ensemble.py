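"""Stacking ensemble with cross-validated metadata, and f1-based evaluation.

Stacking trains base models of different kinds (numeric-feature and image
classifiers), collects their out-of-fold class-probability predictions into
a metadata matrix, and trains a shallow meta-network (one hidden layer of
1024 nodes, dropout 0.3) on that matrix.  Out-of-fold construction — each
sample's metadata row comes from base models that never saw its fold —
prevents the meta-learner from fitting base-model memorization.

Evaluation follows a stratified protocol: an 80/20 outer split, stratified
5-fold cross-validation on the training 80%, each fold-trained model scored
by macro f1 (the unweighted mean over classes of 2TP / (2TP + FP + FN)) on
the common 20% test set, and the five fold scores summarized by
mean/std/median/min/max.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .nn import Dense, Dropout, Network, ReLU


def f1_score(tp: int, fp: int, fn: int) -> float:
    """f1 = 2TP / (2TP + FP + FN); defined as 0 when the denominator is 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("f1 undefined for all-zero counts; returning 0")
        return 0.0
    return 2 * tp / denom


@dataclass
class ConfusionMatrix:
    """Class-by-class tallies; rows are predicted, columns actual."""

    counts: np.ndarray
    classes: np.ndarray

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.counts.sum() - self.tp - self.fp - self.fn

    def per_class_f1(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.array(
                [f1_score(t, p, n) for t, p, n in zip(self.tp, self.fp, self.fn)]
            )


def confusion_and_macro_f1(predicted, actual, classes=None) -> tuple[ConfusionMatrix, float]:
    """One-vs-rest confusion tallies and the unweighted (macro) mean f1.

    ``classes`` fixes the class universe (all must appear in it); by default
    the union of observed labels is used.
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual label vectors differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([predicted, actual]))
    else:
        classes = np.asarray(classes)
        seen = set(np.unique(np.concatenate([predicted, actual])).tolist())
        unknown = seen - set(classes.tolist())
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    index = {c: i for i, c in enumerate(classes.tolist())}
    counts = np.zeros((classes.size, classes.size), dtype=int)
    for p, a in zip(predicted, actual):
        counts[index[p], index[a]] += 1
    cm = ConfusionMatrix(counts=counts, classes=classes)
    return cm, float(cm.per_class_f1().mean())


def stratified_kfold(labels, k_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Fold id per sample; folds preserve class proportions (counts per class
    differ by at most one across folds)."""
    labels = np.asarray(labels)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k_folds:
        warnings.warn(
            f"some class has fewer than {k_folds} members; folds are best-effort"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(labels.size, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
            fold_of[test_idx] = fold
    return fold_of


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

@dataclass
class MetaFeatures:
    """Out-of-fold base-model probability matrix, columns ordered (model, class)."""

    matrix: np.ndarray
    fold_of: np.ndarray | None
    n_folds: int
    classes: np.ndarray
    model_names: tuple[str, ...]


@dataclass
class MetaNetConfig:
    hidden_nodes: int = 1024
    dropout_rate: float = 0.3
    n_layers: int = 1
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1


def _aligned_proba(model, x: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Model probabilities re-indexed onto the global class order."""
    probs = model.predict_proba(x)
    out = np.zeros((probs.shape[0], classes.size))
    pos = {c: i for i, c in enumerate(classes.tolist())}
    for j, c in enumerate(np.asarray(model.classes_).tolist()):
        out[:, pos[c]] = probs[:, j]
    return out


def make_meta_features(
    base_models: list[tuple[str, object, np.ndarray]],
    labels,
    n_folds: int = 5,
    seed: int = 0,
) -> MetaFeatures:
    """Cross-validated metadata: per fold, base models trained on the other
    folds predict the held-out fold.

    ``base_models`` is a list of (name, unfitted estimator factory, input
    array) triples; each factory is called per fold and must expose
    ``fit(X, y)``, ``predict_proba(X)`` and ``classes_``.  Columns are
    ordered model-major, class-minor.
    """
    if not base_models:
        raise ValueError("need at least one base model")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    fold_of = stratified_kfold(labels, k_folds=n_folds, seed=seed)
    matrix = np.zeros((labels.size, len(base_models) * classes.size))
    for fold in range(n_folds):
        hold = fold_of == fold
        for m, (name, factory, x) in enumerate(base_models):
            try:
                model = factory().fit(x[~hold], labels[~hold])
                block = _aligned_proba(model, x[hold], classes)
            except Exception as exc:
                raise RuntimeError(f"base model {name!r} failed on fold {fold}") from exc
            matrix[hold, m * classes.size:(m + 1) * classes.size] = block
    return MetaFeatures(
        matrix=matrix,
        fold_of=fold_of,
        n_folds=n_folds,
        classes=classes,
        model_names=tuple(name for name, _, _ in base_models),
    )


def stacking_fit_predict(
    meta: MetaFeatures,
    labels,
    test_meta: np.ndarray,
    config: MetaNetConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train the shallow meta-network on metadata and predict test rows.

    Returns (predicted labels, class probabilities) for ``test_meta``.
    """
    config = config or MetaNetConfig()
    labels = np.asarray(labels)
    test_meta = np.asarray(test_meta, dtype=float)
    if meta.matrix.shape[0] != labels.size:
        raise ValueError("metadata and labels are misaligned")
    if test_meta.shape[1] != meta.matrix.shape[1]:
        raise ValueError(
            f"test metadata has {test_meta.shape[1]} columns, "
            f"train has {meta.matrix.shape[1]}"
        )
    classes = meta.classes
    codes = np.searchsorted(classes, labels)
    layers = []
    for _ in range(config.n_layers):
        layers += [Dense(config.hidden_nodes), ReLU(), Dropout(config.dropout_rate)]
    net = Network(layers, n_classes=classes.size, seed=seed)
    net.fit(
        meta.matrix,
        codes,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        validation_fraction=config.validation_fraction,
    )
    probs = net.predict_proba(test_meta)
    return classes[probs.argmax(axis=1)], probs


class StackingEnsemble:
    """Two-tier model: base classifiers + meta-network, sklearn-like surface.

    Operates on sample indices so heterogeneous inputs (feature rows and
    image stacks) stay aligned: ``inputs`` maps each base-model name to its
    full input array, and fit/predict take index arrays into those inputs.
    """

    def __init__(
        self,
        base_factories: dict[str, object],
        inputs: dict[str, np.ndarray],
        n_folds: int = 5,
        meta_config: MetaNetConfig | None = None,
        seed: int = 0,
    ):
        if set(base_factories) != set(inputs):
            raise ValueError("base_factories and inputs must share keys")
        self.base_factories = base_factories
        self.inputs = inputs
        self.n_folds = n_folds
        self.meta_config = meta_config or MetaNetConfig()
        self.seed = seed

    def fit(self, train_idx: np.ndarray, labels: np.ndarray) -> "StackingEnsemble":
        self.train_idx_ = np.asarray(train_idx)
        self.labels_ = np.asarray(labels)
        triples = [
            (name, self.base_factories[name], self.inputs[name][self.train_idx_])
            for name in sorted(self.base_factories)
        ]
        self.meta_ = make_meta_features(
            triples, self.labels_, n_folds=self.n_folds, seed=self.seed
        )
        # final base models trained on the full training set produce test metadata
        self.final_models_ = {
            name: self.base_factories[name]().fit(
                self.inputs[name][self.train_idx_], self.labels_
            )
            for name in sorted(self.base_factories)
        }
        return self

    def _test_meta(self, test_idx: np.ndarray) -> np.ndarray:
        blocks = [
            _aligned_proba(
                self.final_models_[name], self.inputs[name][test_idx], self.meta_.classes
            )
            for name in sorted(self.base_factories)
        ]
        return np.hstack(blocks)

    def predict(self, test_idx: np.ndarray) -> np.ndarray:
        preds, _ = stacking_fit_predict(
            self.meta_, self.labels_, self._test_meta(test_idx),
            config=self.meta_config, seed=self.seed,
        )
        return preds


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    fold_f1: list[float]
    mean: float = field(init=False)
    std: float = field(init=False)
    median: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.fold_f1, dtype=float)
        self.mean = float(arr.mean())
        self.std = float(arr.std())
        self.median = float(np.median(arr))
        self.min = float(arr.min())
        self.max = float(arr.max())

    def to_dict(self) -> dict:
        return {
            "fold_f1": list(self.fold_f1),
            "mean": self.mean,
            "std": self.std,
            "median": self.median,
            "min": self.min,
            "max": self.max,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def evaluate_cv(
    fit_predict,
    labels,
    k_folds: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> CvReport:
    """Stratified 80/20 + k-fold protocol around any classifier closure.

    ``fit_predict(train_idx, test_idx)`` must train on the given training
    indices and return predicted labels for the test indices.  The outer
    split is stratified; each of the ``k_folds`` models is trained on k-1
    folds of the training portion and scored by macro f1 on the common test
    portion.
    """
    labels = np.asarray(labels)
    indices = np.arange(labels.size)
    train_idx, test_idx = train_test_split(
        indices, test_size=test_fraction, stratify=labels, random_state=seed
    )
    fold_of = stratified_kfold(labels[train_idx], k_folds=k_folds, seed=seed)
    classes = np.unique(labels)
    scores = []
    for fold in range(k_folds):
        tr = train_idx[fold_of != fold]
        preds = fit_predict(tr, test_idx)
        _, macro = confusion_and_macro_f1(preds, labels[test_idx], classes=classes)
        scores.append(macro)
    return CvReport(fold_f1=scores)
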