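"""A compact feed-forward / convolutional network trained with RMSprop.

This is the in-package learning engine behind the image-branch classifier
and the stacking meta-network: dense, ReLU, dropout, 2-D convolution
(im2col), max-pooling and flatten layers under a softmax cross-entropy head.
It is deliberately small — a few layers on modest inputs, trained
full-batch-or-minibatch on one CPU — and fully seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: tuple = ()

    def init(self, rng: np.random.Generator, in_shape):
        return self.out_shape(in_shape)

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, units: int):
        self.units = units

    def init(self, rng, in_shape):
        (n_in,) = in_shape
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, self.units))
        self.b = np.zeros(self.units)
        self.params = ("W", "b")
        return (self.units,)

    def out_shape(self, in_shape):
        return (self.units,)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def init(self, rng, in_shape):
        self._in_shape = in_shape
        return self.out_shape(in_shape)

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _im2col(x, fh, fw):
    # x: (N, H, W, C) -> (N, H-fh+1, W-fw+1, fh*fw*C)
    n, h, w, c = x.shape
    oh, ow = h - fh + 1, w - fw + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, fh, fw, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    return windows.reshape(n, oh, ow, fh * fw * c)


class Conv2D(Layer):
    """Valid-padding stride-1 convolution on (N, H, W, C) inputs."""

    def __init__(self, filters: int, size: int = 3):
        self.filters = filters
        self.size = size

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h - self.size + 1, w - self.size + 1, self.filters)

    def init(self, rng, in_shape):
        h, w, c = in_shape
        fan_in = self.size * self.size * c
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, self.filters))
        self.b = np.zeros(self.filters)
        self.params = ("W", "b")
        self._c_in = c
        return self.out_shape(in_shape)

    def forward(self, x, train, rng):
        self._cols = _im2col(x, self.size, self.size)
        self._x_shape = x.shape
        return self._cols @ self.W + self.b

    def backward(self, grad):
        n, oh, ow, f = grad.shape
        cols = self._cols.reshape(-1, self.W.shape[0])
        g = grad.reshape(-1, f)
        self.dW = cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, oh, ow, self.size, self.size, self._c_in)
        dx = np.zeros(self._x_shape)
        for i in range(self.size):
            for j in range(self.size):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling (input dims must be even)."""

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h // 2, w // 2, c)

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        xr = x[:, : h // 2 * 2, : w // 2 * 2, :].reshape(n, h // 2, 2, w // 2, 2, c)
        self._xr = xr
        out = xr.max(axis=(2, 4))
        self._argmask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, grad):
        g = self._argmask * grad[:, :, None, :, None, :]
        # split ties evenly so gradient mass is conserved
        ties = self._argmask.sum(axis=(2, 4), keepdims=True)
        g = g / ties
        n, hh, _, ww, _, c = g.shape
        return g.reshape(n, hh * 2, ww * 2, c)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class RMSprop:
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers):
        for li, layer in enumerate(layers):
            for p in layer.params:
                g = getattr(layer, "d" + p)
                c = self.cache.setdefault(li, {}).setdefault(p, np.zeros_like(g))
                c *= self.rho
                c += (1 - self.rho) * g * g
                getattr(layer, p)[...] -= self.lr * g / (np.sqrt(c) + self.eps)


class Network:
    """Sequential network with a softmax cross-entropy head.

    ``fit`` shuffles minibatches with a seeded generator; when a validation
    fraction is given, the best-validation-loss weights within the epoch
    budget are restored (early stopping with patience).
    """

    def __init__(self, layers: list[Layer], n_classes: int, seed: int = 0):
        self.layers = list(layers) + [Dense(n_classes)]
        self.n_classes = n_classes
        self.seed = seed
        self._built = False

    def _build(self, in_shape):
        rng = np.random.default_rng(self.seed)
        shape = in_shape
        for layer in self.layers:
            shape = layer.init(rng, shape)
        self._rng = np.random.default_rng(self.seed + 1)
        self._built = True

    def _forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train, self._rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return softmax(self._forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        batch_size: int = 64,
        lr: float = 1e-3,
        validation_fraction: float = 0.0,
        patience: int = 8,
    ) -> list[float]:
        """Train with RMSprop; returns the per-epoch training loss trace."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if not self._built:
            self._build(x.shape[1:])
        opt = RMSprop(lr=lr)
        rng = np.random.default_rng(self.seed + 2)
        n = x.shape[0]
        x_val = y_val = None
        if validation_fraction > 0 and n >= 10:
            n_val = max(1, int(round(validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            x_val, y_val = x[val_idx], y[val_idx]
            x, y = x[tr_idx], y[tr_idx]
            n = x.shape[0]
        onehot = np.eye(self.n_classes)[y]
        losses: list[float] = []
        best_val = np.inf
        best_weights = None
        stale = 0
        for _ in range(epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                logits = self._forward(x[idx], train=True)
                probs = softmax(logits)
                eps = 1e-12
                epoch_loss += -np.log(probs[np.arange(idx.size), y[idx]] + eps).sum()
                grad = (probs - onehot[idx]) / idx.size
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(self.layers)
            losses.append(epoch_loss / n)
            if x_val is not None:
                val_probs = self.predict_proba(x_val)
                val_loss = -np.log(
                    val_probs[np.arange(y_val.size), y_val] + 1e-12
                ).mean()
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = [
                        {p: getattr(l, p).copy() for p in l.params} for l in self.layers
                    ]
                    stale = 0
                else:
                    stale += 1
                    if stale >= patience:
                        break
        if best_weights is not None:
            for layer, saved in zip(self.layers, best_weights):
                for p, w in saved.items():
                    getattr(layer, p)[...] = w
        return losses
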