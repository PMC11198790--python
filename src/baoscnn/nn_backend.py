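"""Compact NumPy convolutional-network backend.

Implements exactly the layer vocabulary the blueprint decoder needs —
same-padded convolution (im2col over BLAS matmul), ReLU, max pooling,
dropout on the flattened features, and a dense softmax head — trained with
minibatch stochastic gradient descent with momentum on the cross-entropy
loss.  Tensors are NHWC ``float64``.  Small and dependency-free by design:
the networks searched here are a few convolution blocks on small patches,
where im2col convolution on a CPU is entirely adequate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SGDMomentum", "ConvNet"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patch matrix for a same-padded
    k x k convolution (stride 1)."""
    n, h, w, c = x.shape
    pt = (k - 1) // 2
    pb = k - 1 - pt
    xp = np.pad(x, ((0, 0), (pt, pb), (pt, pb), (0, 0)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, h, w, k, k, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
        writeable=False,
    )
    return windows.reshape(n, h, w, k * k * c)


def _col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back."""
    n, h, w, c = shape
    pt = (k - 1) // 2
    pb = k - 1 - pt
    out = np.zeros((n, h + k - 1, w + k - 1, c))
    cols = cols.reshape(n, h, w, k, k, c)
    for di in range(k):
        for dj in range(k):
            out[:, di : di + h, dj : dj + w, :] += cols[:, :, :, di, dj, :]
    return out[:, pt : pt + h, pt : pt + w, :]


class _Conv:
    """Same-padded k x k convolution, stride 1, He-initialised."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (k * k * c_in))
        self.w = rng.normal(0.0, scale, size=(k * k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = _im2col(x, self.k)
        if train:
            self._cols = cols
            self._shape = x.shape
        return cols @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c_out = grad.shape
        g2 = grad.reshape(-1, c_out)
        self.gw = self._cols.reshape(-1, self.w.shape[0]).T @ g2
        self.gb = g2.sum(axis=0)
        gcols = (g2 @ self.w.T).reshape(n, h, w, -1)
        return _col2im(gcols, self._shape, self.k)

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class _MaxPool:
    """Non-overlapping p x p max pooling (input cropped to a multiple of p)."""

    def __init__(self, p: int):
        self.p = p

    def forward(self, x, train):
        n, h, w, c = x.shape
        p = self.p
        ho, wo = h // p, w // p
        xc = x[:, : ho * p, : wo * p, :].reshape(n, ho, p, wo, p, c)
        out = xc.max(axis=(2, 4))
        if train:
            self._shape = x.shape
            self._mask = xc == out[:, :, None, :, None, :]
            # break ties: keep only the first max per window
            flat = self._mask.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, p * p)
            first = np.argmax(flat, axis=-1)
            only = np.zeros_like(flat)
            np.put_along_axis(only, first[..., None], 1, axis=-1)
            self._mask = only.reshape(n, ho, wo, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        p = self.p
        ho, wo = h // p, w // p
        g = self._mask * grad[:, :, None, :, None, :]
        out = np.zeros(self._shape)
        out[:, : ho * p, : wo * p, :] = g.reshape(n, ho * p, wo * p, c)
        return out

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def params(self):
        return []


class _Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


@dataclass
class SGDMomentum:
    """Classical momentum SGD: v <- mu v - lr g; w <- w + v.

    Gradients are clipped by global norm (default 5) before the update;
    without it, learning rates at the top of the searched range can throw
    a freshly initialised network onto the dead-ReLU plateau on the first
    few minibatches.
    """

    lr: float
    momentum: float
    max_norm: float = 5.0
    _velocity: dict = field(default_factory=dict)

    def step(self, layers) -> None:
        total = 0.0
        for layer in layers:
            for _, gname in layer.params():
                total += float((getattr(layer, gname) ** 2).sum())
        scale = min(1.0, self.max_norm / (math.sqrt(total) + 1e-12))
        for layer in layers:
            for idx, (param, gname) in enumerate(layer.params()):
                key = (id(layer), idx)
                grad = getattr(layer, gname) * scale
                v = self._velocity.get(key)
                v = -self.lr * grad if v is None else self.momentum * v - self.lr * grad
                self._velocity[key] = v
                param += v


class ConvNet:
    """A stack of [conv -> ReLU -> optional max-pool] blocks, flatten,
    dropout, dense softmax head.

    ``blocks`` is a list of (kernel, filters, pool) with ``pool = 1``
    meaning no pooling for that block.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_classes: int,
        blocks: list[tuple[int, int, int]],
        dropout: float,
        lr: float,
        momentum: float,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        h, w, c = input_shape
        self.layers: list = []
        for kernel, filters, pool in blocks:
            self.layers.append(_Conv(kernel, c, filters, rng))
            self.layers.append(_ReLU())
            if pool > 1:
                self.layers.append(_MaxPool(pool))
                h, w = h // pool, w // pool
            c = filters
        self.layers.append(_Flatten())
        self.layers.append(_Dropout(dropout, rng))
        self.layers.append(_Dense(h * w * c, n_classes, rng))
        self.optimizer = SGDMomentum(lr=lr, momentum=momentum)
        self.n_classes = n_classes
        self._rng = rng

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def train_epoch(self, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
        """One pass of minibatch SGD; returns the mean training loss."""
        n = x.shape[0]
        order = self._rng.permutation(n)
        batch_size = max(1, min(batch_size, n))
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = self._forward(xb, train=True)
            probs = self._softmax(logits)
            eps = 1e-12
            total += -np.log(probs[np.arange(len(yb)), yb] + eps).sum()
            grad = probs
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            for layer in reversed(self.layers):
                grad = layer.backward(grad)
            self.optimizer.step(self.layers)
        return total / n

    def state(self) -> list[np.ndarray]:
        """Deep copy of all trainable parameters, in layer order."""
        return [p.copy() for layer in self.layers for p, _ in layer.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = [p for layer in self.layers for p, _ in layer.params()]
        for param, saved in zip(params, state):
            param[...] = saved

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self._softmax(self._forward(x, train=False))
        eps = 1e-12
        return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits = self._forward(x[start : start + batch_size], train=False)
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out)
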