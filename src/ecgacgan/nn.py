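"""Minimal numpy neural-network kit for 1D signals.

Implements exactly the pieces the generation and recognition networks need:
1D convolution (same padding), max pooling, dense layers, leaky-rectifier /
tanh activations, dropout, a class-embedding table, softmax cross-entropy and
binary cross-entropy losses, and an Adam optimiser.  Backpropagation is coded
by hand layer-by-layer; all randomness flows through an explicit
``numpy.random.Generator`` so training is bit-reproducible given a seed.

Conventions: convolutional tensors are ``(batch, channels, length)`` float32;
dense tensors are ``(batch, features)``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "Dense",
    "LeakyReLU",
    "Tanh",
    "MaxPool1d",
    "Flatten",
    "Dropout",
    "Embedding",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_ce",
    "bce_with_logits",
]

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv1d(Layer):
    """Same-padded 1D convolution, weight shape (c_out, c_in, k)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, k)))
        self.b = Param(np.zeros(c_out))
        self.k = k
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (b, c, l, k) view -> (b*l, c*k) matrix
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(b * l, c * self.k)
        self._cols = cols
        self._shape = (b, c, l)
        w2 = self.w.value.reshape(self.w.value.shape[0], -1).T  # (c*k, c_out)
        out = cols @ w2 + self.b.value
        return out.reshape(b, l, -1).transpose(0, 2, 1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, l = self._shape
        c_out = g.shape[1]
        g2 = g.transpose(0, 2, 1).reshape(b * l, c_out)
        self.w.grad += (self._cols.T @ g2).T.reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=0)
        w2 = self.w.value.reshape(c_out, -1)  # (c_out, c*k)
        gcols = (g2 @ w2).reshape(b, l, c, self.k)
        p = self.k // 2
        gxp = np.zeros((b, c, l + 2 * p), dtype=DTYPE)
        for i in range(self.k):
            gxp[:, :, i : i + l] += gcols[:, :, :, i].transpose(0, 2, 1)
        return gxp[:, :, p : p + l]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.alpha * g)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * (1.0 - self._y**2)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is truncated."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        lo = l // self.size
        xt = x[:, :, : lo * self.size].reshape(b, c, lo, self.size)
        self._arg = xt.argmax(axis=3)
        self._shape = (b, c, l)
        return xt.max(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, l = self._shape
        lo = g.shape[2]
        gx = np.zeros((b, c, lo, self.size), dtype=DTYPE)
        bi, ci, li = np.ogrid[:b, :c, :lo]
        gx[bi, ci, li, self._arg] = g
        out = np.zeros((b, c, l), dtype=DTYPE)
        out[:, :, : lo * self.size] = gx.reshape(b, c, lo * self.size)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only while ``training`` is True."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout fraction must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask.astype(DTYPE)


class Embedding(Layer):
    """Lookup table mapping integer ids to dense vectors."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.table = Param(rng.normal(0.0, 1.0, size=(n, dim)))
        self._ids: np.ndarray | None = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = np.asarray(ids, dtype=np.int64)
        if self._ids.min() < 0 or self._ids.max() >= self.table.value.shape[0]:
            raise ValueError("class id out of range")
        return self.table.value[self._ids]

    def backward(self, g: np.ndarray) -> np.ndarray:
        np.add.at(self.table.grad, self._ids, g)
        return g  # no meaningful input gradient

    def params(self) -> list[Param]:
        return [self.table]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def set_training(self, flag: bool) -> None:
        for layer in self.layers:
            layer.training = flag
            if isinstance(layer, Sequential):
                layer.set_training(flag)


class Adam:
    """Adaptive-moment optimiser over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_ce(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    b = logits.shape[0]
    ll = -np.log(np.clip(p[np.arange(b), labels], 1e-12, None))
    g = p.copy()
    g[np.arange(b), labels] -= 1.0
    return float(ll.mean()), (g / b).astype(DTYPE)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores and gradient w.r.t. logits."""
    x = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    s = 1.0 / (1.0 + np.exp(-x))
    return float(loss.mean()), ((s - t) / x.size).astype(DTYPE)
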