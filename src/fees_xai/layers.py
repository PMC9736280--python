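"""Building blocks for the segmentation network, implemented on NumPy.

Each layer exposes ``forward(x, training)`` and ``backward(dy)`` with
explicit gradients.  Tensors are NHWC float32 throughout: with channels
last, a same-padding convolution reduces to nine shifted matrix products on
contiguous memory, which keeps the heavy lifting in BLAS without an
im2col copy.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "PReLU",
    "MaxPool2D",
    "UpsampleNearest2D",
    "Dropout2D",
    "Sigmoid",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers to persist (e.g. batchnorm running stats)."""
        return {}


class Conv2D(Layer):
    """k×k convolution with zero padding and stride 1 (spatial size preserved).

    Weights are stored as (k, k, c_in, c_out); the forward pass accumulates
    ``x[:, u:u+H, v:v+W, :] @ W[u, v]`` over the k² kernel offsets.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out)))
        self.bias = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        out = np.zeros((n, h, w, self.c_out), dtype=np.float32)
        for u in range(k):
            for v in range(k):
                out += xp[:, u : u + h, v : v + w, :] @ self.weight.value[u, v]
        out += self.bias.value
        if training:
            self._xp = xp
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        k, p = self.k, self.k // 2
        xp = self._xp
        dy_flat = dy.reshape(-1, self.c_out)
        for u in range(k):
            for v in range(k):
                sl = np.ascontiguousarray(xp[:, u : u + h, v : v + w, :]).reshape(-1, self.c_in)
                self.weight.grad[u, v] += sl.T @ dy_flat
        self.bias.grad += dy_flat.sum(axis=0)
        self._xp = None
        # dx = dy convolved with the spatially flipped, transposed kernel.
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0))) if p else dy
        dx = np.zeros((n, h, w, self.c_in), dtype=np.float32)
        for u in range(k):
            for v in range(k):
                dx += dyp[:, u : u + h, v : v + w, :] @ self.weight.value[k - 1 - u, k - 1 - v].T
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._xhat: np.ndarray | None = None
        self._invstd: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * invstd
        if training:
            self._xhat, self._invstd = xhat, invstd
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (invstd / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        self._xhat = None
        return dx.astype(np.float32)


class PReLU(Layer):
    """Parametric ReLU with one learnable slope per channel (init 0.25)."""

    def __init__(self, c: int) -> None:
        self.slope = Param(np.full(c, 0.25))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.slope]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return np.where(x > 0, x, self.slope.value * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        self.slope.grad += np.where(neg, x * dy, 0.0).sum(axis=(0, 1, 2))
        self._x = None
        return np.where(neg, self.slope.value * dy, dy).astype(np.float32)


class MaxPool2D(Layer):
    """2×2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        idx = xr.argmax(axis=-1)
        if training:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        return (
            out.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class UpsampleNearest2D(Layer):
    """×2 nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(np.float32)


class Dropout2D(Layer):
    """Channel-wise (spatial) dropout with inverted scaling; training only."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0], 1, 1, x.shape[3])) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        if training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return (dy * y * (1.0 - y)).astype(np.float32)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
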