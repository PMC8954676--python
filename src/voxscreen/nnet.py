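"""Minimal feed-forward 3D convolutional network in NumPy.

Implements exactly the layer set the affinity scorer needs — 3D
convolution (im2col + BLAS matmul), 2x2x2 max-pooling, flatten, dense —
with reverse-mode gradients and an Adam optimizer. Everything runs in
float32 on the CPU; parameter initialization and mini-batch shuffling are
deterministic functions of explicit seeds.

Gradient correctness is guarded by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = ["Conv3D", "MaxPool3D", "Flatten", "Dense", "Adam", "forward_shape"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv3D:
    """Valid (no padding) 3D convolution with optional ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int = 1, activation: str = "relu",
                 rng: np.random.Generator | None = None) -> None:
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.stride = stride
        self.activation = activation
        fan_in = in_channels * kernel ** 3
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale, size=(fan_in, filters)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        c, d, h, w = in_shape
        k, s = self.kernel, self.stride
        if min(d, h, w) < k:
            raise ValueError(f"kernel {k} exceeds input extent {(d, h, w)}")
        return (self.filters, (d - k) // s + 1, (h - k) // s + 1, (w - k) // s + 1)

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        b, c, d, h, w = x.shape
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]
        do, ho, wo = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(b * do * ho * wo, c * k ** 3)
        z = cols @ self.W + self.b
        pre = None
        if self.activation == "relu":
            pre = z
            z = _relu(z)
        if need_grad:
            self._cache = (cols, x.shape, (do, ho, wo), pre)
        out = z.reshape(b, do, ho, wo, self.filters).transpose(0, 4, 1, 2, 3)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (do, ho, wo), pre = self._cache
        b, c, d, h, w = x_shape
        k, s = self.kernel, self.stride
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.filters)
        if pre is not None:
            dflat = dflat * (pre > 0)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W.T
        dcols = dcols.reshape(b, do, ho, wo, c, k, k, k)
        dx = np.zeros(x_shape, dtype=np.float32)
        for a, bb, cc in product(range(k), repeat=3):
            dx[:, :, a:a + s * do:s, bb:bb + s * ho:s, cc:cc + s * wo:s] += \
                dcols[:, :, :, :, :, a, bb, cc].transpose(0, 4, 1, 2, 3)
        self._cache = None
        return dx


class MaxPool3D:
    """2x2x2 max pooling with stride 2; odd trailing voxels are cropped."""

    params: list[np.ndarray] = []

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        c, d, h, w = in_shape
        if min(d, h, w) < 2:
            raise ValueError(f"pooling needs extent >= 2, got {(d, h, w)}")
        return (c, d // 2, h // 2, w // 2)

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xc = x[:, :, :d2 * 2, :h2 * 2, :w2 * 2]
        blocks = xc.reshape(b, c, d2, 2, h2, 2, w2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d2, h2, w2, 8)
        arg = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
        if need_grad:
            self._cache = (x.shape, arg)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, arg = self._cache
        b, c, d, h, w = x_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dblocks = np.zeros((b, c, d2, h2, w2, 8), dtype=np.float32)
        np.put_along_axis(dblocks, arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape, dtype=np.float32)
        dblocks = dblocks.reshape(b, c, d2, h2, w2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d2 * 2, h2 * 2, w2 * 2)
        dx[:, :, :d2 * 2, :h2 * 2, :w2 * 2] = dblocks
        self._cache = None
        return dx


class Flatten:
    params: list[np.ndarray] = []

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return (int(np.prod(in_shape)),)

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    """Fully connected layer with optional ReLU."""

    def __init__(self, in_features: int, units: int, activation: str = "relu",
                 rng: np.random.Generator | None = None) -> None:
        self.units = units
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, size=(in_features, units)).astype(np.float32)
        self.b = np.zeros(units, dtype=np.float32)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        if len(in_shape) != 1:
            raise ValueError("dense layer needs flattened input")
        if in_shape[0] != self.W.shape[0]:
            raise ValueError(
                f"dense expects {self.W.shape[0]} features, got {in_shape[0]}")
        return (self.units,)

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        if need_grad:
            self._cache = (x, z if self.activation == "relu" else None)
        return _relu(z) if self.activation == "relu" else z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, pre = self._cache
        if pre is not None:
            dout = dout * (pre > 0)
        self.dW = x.T @ dout
        self.db = dout.sum(axis=0)
        self._cache = None
        return dout @ self.W.T


class Adam:
    """Adam optimizer over an explicit parameter/gradient list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def forward_shape(layers: list, in_shape: tuple[int, ...]) -> tuple[int, ...]:
    """Propagate a (C, D, H, W) shape through a layer stack."""
    shape = in_shape
    for layer in layers:
        shape = layer.out_shape(shape)
    return shape
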