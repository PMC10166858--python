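"""Minimal deterministic feed-forward network primitives (numpy).

Just enough machinery for the two autoencoder architectures in
:mod:`lsuss.autoencoder`: dense layers (optionally weight-tied to an encoder
layer), 1-D convolutions and transposed convolutions, sigmoid/ReLU
activations, mean-squared-error loss, and Adam.  Everything is seeded
through a single :class:`numpy.random.Generator`, so training is bitwise
reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Param", "Dense", "DenseTransposed", "Conv1d", "ConvTranspose1d",
           "Flatten", "Unflatten", "Sigmoid", "ReLU", "Identity",
           "Sequential", "Adam", "mse_loss"]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Layer:
    params: tuple[Param, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Param(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.params = (self.W, self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class DenseTransposed(Layer):
    """Dense layer sharing (the transpose of) another Dense layer's weights.

    If the tied layer maps ``a -> b`` this layer maps ``b -> a`` via
    ``x @ W.T + b`` with its own bias; gradients accumulate into the shared
    weight.
    """

    def __init__(self, tied: Dense):
        self._W = tied.W
        self.b = Param(np.zeros(tied.W.value.shape[0]))
        self.params = (self._W, self.b)

    def forward(self, x):
        self._x = x
        return x @ self._W.value.T + self.b.value

    def backward(self, dy):
        self._W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self._W.value


class Conv1d(Layer):
    """1-D convolution over ``(batch, channels, length)`` input."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.W = Param(_glorot(rng, c_in * kernel, c_out, (c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self.params = (self.W, self.b)

    def out_length(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        B, C, L = x.shape
        Lout = self.out_length(L)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        idx = (np.arange(Lout) * s)[:, None] + np.arange(k)  # (Lout, k)
        cols = xp[:, :, idx]                                  # (B, C, Lout, k)
        self._cols, self._Lin = cols, L
        return np.einsum("bctk,ock->bot", cols, self.W.value) + self.b.value[:, None]

    def backward(self, dy):
        k, s, p = self.kernel, self.stride, self.pad
        B, C, Lout, _ = self._cols.shape
        self.W.grad += np.einsum("bot,bctk->ock", dy, self._cols)
        self.b.grad += dy.sum(axis=(0, 2))
        dcols = np.einsum("bot,ock->bctk", dy, self.W.value)
        dxp = np.zeros((B, C, self._Lin + 2 * p))
        base = np.arange(Lout) * s
        for j in range(k):  # positions base+j are unique for stride >= 1
            dxp[:, :, base + j] += dcols[:, :, :, j]
        return dxp[:, :, p:p + self._Lin]


class ConvTranspose1d(Layer):
    """Transposed 1-D convolution (the adjoint of :class:`Conv1d`)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int = 3, stride: int = 2, pad: int = 1,
                 out_pad: int = 1):
        self.kernel, self.stride, self.pad, self.out_pad = kernel, stride, pad, out_pad
        self.W = Param(_glorot(rng, c_in, c_out * kernel, (c_in, c_out, kernel)))
        self.b = Param(np.zeros(c_out))
        self.params = (self.W, self.b)

    def out_length(self, L: int) -> int:
        return (L - 1) * self.stride - 2 * self.pad + self.kernel + self.out_pad

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        B, C, L = x.shape
        Lout = self.out_length(L)
        contrib = np.einsum("bct,cok->botk", x, self.W.value)
        ypad = np.zeros((B, self.W.value.shape[1], Lout + 2 * p))
        base = np.arange(L) * s
        for j in range(k):
            ypad[:, :, base + j] += contrib[:, :, :, j]
        self._x = x
        return ypad[:, :, p:p + Lout] + self.b.value[:, None]

    def backward(self, dy):
        k, s, p = self.kernel, self.stride, self.pad
        B, C, L = self._x.shape
        Lout = dy.shape[2]
        dypad = np.zeros((B, dy.shape[1], Lout + 2 * p))
        dypad[:, :, p:p + Lout] = dy
        base = np.arange(L) * s
        dcontrib = np.stack([dypad[:, :, base + j] for j in range(k)], axis=-1)
        self.W.grad += np.einsum("bct,botk->cok", self._x, dcontrib)
        self.b.grad += dy.sum(axis=(0, 2))
        return np.einsum("botk,cok->bct", dcontrib, self.W.value)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Unflatten(Layer):
    def __init__(self, channels: int, length: int):
        self.channels, self.length = channels, length

    def forward(self, x):
        return x.reshape(x.shape[0], self.channels, self.length)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Identity(Layer):
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class Sequential:
    """An ordered layer stack with shared-parameter-aware bookkeeping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[Param]:
        seen: dict[int, Param] = {}
        for layer in self.layers:
            for p in layer.params:
                seen.setdefault(id(p), p)
        return list(seen.values())


def unique_params(*models: Sequential) -> list[Param]:
    seen: dict[int, Param] = {}
    for model in models:
        for p in model.params:
            seen.setdefault(id(p), p)
    return list(seen.values())


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad * p.grad
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
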