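"""Minimal feed-forward network primitives with explicit backpropagation.

The ordinal promoter-TIF model is a shallow stack: three 1-D convolutions,
dropout, two dense layers, and a specialised output head.  At this size a
small, dependency-free implementation keeps the whole computation inspectable
and deterministic; gradients of every layer are verified against numerical
differentiation in the test suite.

Conventions: convolution inputs are (N, C, L); dense inputs are (N, D);
``forward(x, train=...)`` caches what ``backward(dout)`` needs; parameters
and their gradient buffers are exposed in matching order for the optimizer.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless layers simply override forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding), stride-1 cross-correlation with bias."""

    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        # He initialisation for rectifier networks
        scale = np.sqrt(2.0 / (c_in * width))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, width))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.width = width

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        k = self.width
        L_out = x.shape[2] - k + 1
        if L_out < 1:
            raise ValueError("input shorter than kernel")
        self._idx = np.arange(L_out)[:, None] + np.arange(k)[None, :]
        self._x_col = x[:, :, self._idx]          # (N, C_in, L_out, k)
        self._x_shape = x.shape
        return np.einsum("nclk,ock->nol", self._x_col, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dout):
        self.dW[...] = np.einsum("nol,nclk->ock", dout, self._x_col, optimize=True)
        self.db[...] = dout.sum(axis=(0, 2))
        dx_col = np.einsum("nol,ock->nclk", dout, self.W, optimize=True)
        dx = np.zeros(self._x_shape)
        np.add.at(dx, (slice(None), slice(None), self._idx), dx_col)
        return dx


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.grad_refs = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def snapshot(params: list[np.ndarray]) -> list[np.ndarray]:
    return [p.copy() for p in params]


def restore(params: list[np.ndarray], saved: list[np.ndarray]) -> None:
    for p, s in zip(params, saved):
        p[...] = s
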