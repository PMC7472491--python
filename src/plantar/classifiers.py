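"""Base classifiers: k-NN and CART on numeric features, and the image branch.

The numeric branch follows the textbook constructions exactly — Euclidean
distance k-nearest-neighbor voting (default k = 7) and a CART tree grown by
minimizing the Gini split cost J(k, t_k) = (m_left/m) G_left +
(m_right/m) G_right with midpoint thresholds (default max depth 9).  Tie
rules are deterministic and documented on each operation.

The image branch is a fine-tunable classifier head — FC layer, dropout,
softmax over the nine (left, right) subclasses — on a configurable backbone.
The ``tiny_test`` backbone is a small convolutional network trained from
scratch in this package; the ``vgg16_style`` / ``inception_style`` presets
carry the published fine-tuning hyperparameters and require externally
provided pretrained weights (they raise rather than download).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Conv2D, Dense, Dropout, Flatten, MaxPool2D, Network, ReLU


# ---------------------------------------------------------------------------
# k-nearest neighbors
# ---------------------------------------------------------------------------

@dataclass
class KnnConfig:
    k: int = 7
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance != "euclidean":
            raise ValueError(f"unsupported distance {self.distance!r}")


def euclidean_distance(x, y) -> float:
    """d = sqrt(sum_i (x_i - y_i)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(((x - y) ** 2).sum()))


class KNNClassifier:
    """Majority vote over the k nearest training points.

    Distance ties at the k-th neighbor break by training index order; vote
    ties between classes break by smallest mean distance among the tied
    classes' neighbors, then by class order.
    """

    def __init__(self, config: KnnConfig | None = None):
        self.config = config or KnnConfig()

    def fit(self, x: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        self.x_ = np.asarray(x, dtype=float)
        self.y_ = np.asarray(y)
        if self.x_.shape[0] == 0:
            raise ValueError("empty training set")
        if self.config.k > self.x_.shape[0]:
            raise ValueError(
                f"k={self.config.k} exceeds training size {self.x_.shape[0]}"
            )
        self.classes_ = np.unique(self.y_)
        return self

    def _neighbors(self, q: np.ndarray) -> np.ndarray:
        d = np.sqrt(((self.x_ - q) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(d.size), d))  # index order breaks ties
        return order[: self.config.k], d

    def predict_proba(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        out = np.zeros((queries.shape[0], self.classes_.size))
        for i, q in enumerate(queries):
            nn_idx, _ = self._neighbors(q)
            votes = self.y_[nn_idx]
            for j, c in enumerate(self.classes_):
                out[i, j] = (votes == c).sum() / self.config.k
        return out

    def predict(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        preds = []
        for q in queries:
            nn_idx, d = self._neighbors(q)
            votes = self.y_[nn_idx]
            counts = {c: (votes == c).sum() for c in self.classes_}
            top = max(counts.values())
            tied = [c for c in self.classes_ if counts[c] == top]
            if len(tied) > 1:
                means = {c: d[nn_idx[votes == c]].mean() for c in tied}
                best = min(means.values())
                tied = [c for c in tied if means[c] == best]
            preds.append(tied[0])
        return np.array(preds)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "k": self.config.k,
            "distance": self.config.distance,
            "x": self.x_.tolist(),
            "y": self.y_.tolist(),
        }
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "KNNClassifier":
        doc = json.loads(Path(path).read_text())
        model = cls(KnnConfig(k=doc["k"], distance=doc["distance"]))
        return model.fit(np.array(doc["x"]), np.array(doc["y"]))


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

@dataclass
class CartConfig:
    max_depth: int = 9
    criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.criterion != "gini":
            raise ValueError(f"unsupported criterion {self.criterion!r}")


@dataclass
class SplitCandidate:
    feature_index: int
    threshold_tk: float
    cost_J: float
    m_left: int
    m_right: int
    g_left: float
    g_right: float

    def __post_init__(self) -> None:
        m = self.m_left + self.m_right
        expect = (self.m_left / m) * self.g_left + (self.m_right / m) * self.g_right
        if abs(expect - self.cost_J) > 1e-9:
            raise ValueError("cost_J inconsistent with weighted child impurities")


def gini_impurity(class_proportions) -> float:
    """G = 1 - sum_k p_k^2; zero iff the node is pure."""
    p = np.asarray(list(class_proportions), dtype=float)
    if p.size == 0 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    return float(1.0 - (p**2).sum())


def _gini_from_counts(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
    g = 1.0 - (p**2).sum(axis=-1)
    return np.where(totals[..., 0] > 0, g, 0.0)


def best_split(x: np.ndarray, y_codes: np.ndarray, n_classes: int) -> SplitCandidate | None:
    """Exhaustive best Gini split over all features and midpoint thresholds.

    Returns None when no candidate reduces the node impurity.  Cost ties
    break to the smallest feature index, then smallest threshold.
    """
    m = y_codes.size
    parent = _gini_from_counts(np.bincount(y_codes, minlength=n_classes)[None, :])[0]
    best: SplitCandidate | None = None
    for f in range(x.shape[1]):
        col = x[:, f]
        order = np.argsort(col, kind="stable")
        xs, ys = col[order], y_codes[order]
        onehot = np.eye(n_classes, dtype=int)[ys]
        prefix = np.cumsum(onehot, axis=0)  # counts up to and incl. position i
        boundaries = np.flatnonzero(np.diff(xs) > 0)
        if boundaries.size == 0:
            continue
        left = prefix[boundaries]
        right = prefix[-1] - left
        m_left = boundaries + 1
        m_right = m - m_left
        J = (m_left / m) * _gini_from_counts(left) + (m_right / m) * _gini_from_counts(right)
        thresholds = (xs[boundaries] + xs[boundaries + 1]) / 2.0
        i = int(np.lexsort((thresholds, J))[0])
        if J[i] < parent - 1e-12 and (best is None or J[i] < best.cost_J - 1e-12):
            best = SplitCandidate(
                feature_index=f,
                threshold_tk=float(thresholds[i]),
                cost_J=float(J[i]),
                m_left=int(m_left[i]),
                m_right=int(m_right[i]),
                g_left=float(_gini_from_counts(left[i][None, :])[0]),
                g_right=float(_gini_from_counts(right[i][None, :])[0]),
            )
    return best


class CartClassifier:
    """Binary Gini decision tree; growth stops at max_depth, purity, or when
    no split reduces impurity."""

    def __init__(self, config: CartConfig | None = None):
        self.config = config or CartConfig()

    def fit(self, x: np.ndarray, y: np.ndarray) -> "CartClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if y.size == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.tree_ = self._grow(x, codes, depth=0)
        return self

    def _grow(self, x, codes, depth):
        counts = np.bincount(codes, minlength=self.classes_.size)
        probs = counts / counts.sum()
        if depth >= self.config.max_depth or counts.max() == counts.sum():
            return {"leaf": True, "probs": probs.tolist()}
        cand = best_split(x, codes, self.classes_.size)
        if cand is None:
            return {"leaf": True, "probs": probs.tolist()}
        go_left = x[:, cand.feature_index] <= cand.threshold_tk
        return {
            "leaf": False,
            "feature": cand.feature_index,
            "threshold": cand.threshold_tk,
            "cost_J": cand.cost_J,
            "left": self._grow(x[go_left], codes[go_left], depth + 1),
            "right": self._grow(x[~go_left], codes[~go_left], depth + 1),
        }

    @property
    def depth(self) -> int:
        def _d(node):
            return 0 if node["leaf"] else 1 + max(_d(node["left"]), _d(node["right"]))

        return _d(self.tree_)

    def _node_probs(self, q):
        node = self.tree_
        while not node["leaf"]:
            node = node["left"] if q[node["feature"]] <= node["threshold"] else node["right"]
        return node["probs"]

    def predict_proba(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        return np.array([self._node_probs(q) for q in queries])

    def predict(self, queries: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(queries).argmax(axis=1)]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "max_depth": self.config.max_depth,
            "classes": self.classes_.tolist(),
            "tree": self.tree_,
        }))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CartClassifier":
        doc = json.loads(Path(path).read_text())
        model = cls(CartConfig(max_depth=doc["max_depth"]))
        model.classes_ = np.array(doc["classes"])
        model.tree_ = doc["tree"]
        return model


# ---------------------------------------------------------------------------
# Image branch
# ---------------------------------------------------------------------------

class PretrainedWeightsUnavailable(RuntimeError):
    pass


@dataclass
class FinetuneConfig:
    """Image-classifier configuration.

    ``vgg16_style`` freezes the backbone through block 4 and fine-tunes from
    block 5 with a 1000-node FC head; ``inception_style`` fine-tunes the
    whole inception stack with a 1024-node head.  Both use dropout 0.6 and
    RMSprop at learning rate 1e-5 on 224x224x3 inputs over 9 subclasses.
    ``tiny_test`` is a from-scratch convolutional backbone for small inputs.
    """

    backbone: str = "tiny_test"
    input_size: int = 224
    freeze_boundary: str | None = None
    fc_nodes: int = 1000
    dropout_rate: float = 0.6
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-5
    n_classes: int = 9
    pretrained_weights: str | None = None
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in ("vgg16_style", "inception_style", "tiny_test"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def finetune_preset(name: str, **overrides) -> FinetuneConfig:
    """Named image-branch configurations."""
    presets = {
        "vgg16_style": dict(
            backbone="vgg16_style", input_size=224, freeze_boundary="block4",
            fc_nodes=1000, dropout_rate=0.6, learning_rate=1e-5,
        ),
        "inception_style": dict(
            backbone="inception_style", input_size=224, freeze_boundary=None,
            fc_nodes=1024, dropout_rate=0.6, learning_rate=1e-5,
        ),
        "tiny_test": dict(
            backbone="tiny_test", input_size=48, fc_nodes=64,
            dropout_rate=0.3, learning_rate=1e-3,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}")
    return FinetuneConfig(**{**presets[name], **overrides})


class ImageClassifier:
    """Classifier head (FC -> dropout -> softmax) on a configurable backbone."""

    def __init__(self, config: FinetuneConfig | None = None):
        self.config = config or finetune_preset("tiny_test")
        if self.config.backbone != "tiny_test" and not self.config.pretrained_weights:
            raise PretrainedWeightsUnavailable(
                f"backbone {self.config.backbone!r} needs ImageNet-pretrained "
                "weights; supply FinetuneConfig.pretrained_weights with a local "
                "checkpoint path (weights are never downloaded implicitly)"
            )

    def _build(self, in_shape) -> Network:
        cfg = self.config
        layers = [
            Conv2D(8, 3), ReLU(), MaxPool2D(), Flatten(),
            Dense(cfg.fc_nodes), ReLU(), Dropout(cfg.dropout_rate),
        ]
        return Network(layers, n_classes=cfg.n_classes, seed=cfg.seed)

    @staticmethod
    def _prep(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        # per-image contrast normalization
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        std = x.std(axis=(1, 2, 3), keepdims=True)
        std[std == 0] = 1.0
        return (x - mean) / std

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "ImageClassifier":
        x = self._prep(images)
        self.classes_ = np.unique(labels)
        codes = np.searchsorted(self.classes_, labels)
        self.net_ = self._build(x.shape[1:])
        self.net_.fit(
            x, codes,
            epochs=self.config.epochs,
            batch_size=self.config.batch_size,
            lr=self.config.learning_rate,
        )
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.net_.predict_proba(self._prep(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(images).argmax(axis=1)]


def cnn_classify(
    train_images: np.ndarray, labels: np.ndarray, config: FinetuneConfig | None = None
) -> ImageClassifier:
    """Train the image-branch classifier; returns the fitted model."""
    return ImageClassifier(config).fit(train_images, labels)


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

#: published search ranges: k in [1, 1000], max_depth in [0, 10]
DEFAULT_RANGES = {"knn": (1, 1000), "cart": (0, 10)}


def tune_hyperparameter(
    objective,
    search_range: tuple[int, int],
    strategy: str = "grid",
    seed: int = 0,
    n_calls: int = 20,
) -> tuple[int, list[tuple[int, float]]]:
    """Maximize ``objective(candidate)`` over an integer range.

    ``grid`` evaluates every candidate; ``random`` samples ``n_calls``
    candidates; ``bayesian`` delegates to scikit-optimize when installed and
    otherwise falls back to random search with a warning.  Ties go to the
    smallest candidate.  Returns (best candidate, full evaluation trace).
    """
    lo, hi = search_range
    if lo > hi:
        raise ValueError(f"invalid range [{lo}, {hi}]")
    if strategy == "bayesian":
        try:
            import skopt  # noqa: F401
        except ImportError:
            warnings.warn("scikit-optimize not installed; using random search")
            strategy = "random"
    if strategy == "grid":
        candidates = list(range(lo, hi + 1))
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        candidates = sorted(set(rng.integers(lo, hi + 1, size=n_calls).tolist()))
    elif strategy == "bayesian":
        from skopt import gp_minimize

        trace: list[tuple[int, float]] = []

        def _neg(params):
            v = int(params[0])
            score = float(objective(v))
            trace.append((v, score))
            return -score

        gp_minimize(_neg, [(lo, hi)], n_calls=max(n_calls, 10), random_state=seed)
        best_score = max(s for _, s in trace)
        best = min(v for v, s in trace if s == best_score)
        return best, trace
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    trace = [(v, float(objective(v))) for v in candidates]
    best_score = max(s for _, s in trace)
    best = min(v for v, s in trace if s == best_score)
    return best, trace
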