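"""Minimal NumPy convolutional-network layers with hand-written backprop.

Just enough machinery for an image-to-image encoder–decoder: 'same'
zero-padded k×k convolution (im2col + GEMM), ReLU, 2×2 stride-2 max
pooling, 2×2 stride-2 transposed convolution, dropout, and an Adam
optimizer. Everything is float32 and deterministic given the seeds
passed in; there is no autograd — each layer caches what its backward
pass needs.

Tensors are (batch, channels, height, width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Param", "Conv2D", "ReLU", "MaxPool2", "ConvTranspose2", "Dropout", "Adam"]


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.ascontiguousarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D:
    """k×k convolution, stride 1, zero 'same' padding, optional bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name: str = "conv"):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = Param(f"{name}.W", _he_init(rng, (c_out, c_in * k * k), c_in * k * k))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, C*k*k, H*W) with (c, ki, kj) ordering
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * self.k * self.k, h * w)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = self._im2col(x)
        y = np.einsum("of,bfn->bon", self.W.value, cols, optimize=True)
        y += self.b.value[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(b, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        b, c, h, w = xshape
        dyf = dy.reshape(b, self.c_out, h * w)
        self.W.grad += np.einsum("bon,bfn->of", dyf, cols, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,bon->bfn", self.W.value, dyf, optimize=True)
        dcols = dcols.reshape(b, c, self.k, self.k, h, w)
        p = self.k // 2
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, di, dj]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2×2 window, stride 2; ties route the gradient to the first maximum."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even dims, got {(h, w)}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = np.argmax(xr, axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        b, c, h, w = xshape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(b, c, h, w)


class ConvTranspose2:
    """2×2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "upconv"):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(f"{name}.W", _he_init(rng, (c_in, c_out, 2, 2), c_in))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        y = np.einsum("bchw,codq->bohdwq", x, self.W.value, optimize=True)
        y = y.reshape(b, self.c_out, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        self._cache = x
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        b, o, h2, w2 = dy.shape
        dyv = dy.reshape(b, o, h2 // 2, 2, w2 // 2, 2)
        self.W.grad += np.einsum("bchw,bohdwq->codq", x, dyv, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("bohdwq,codq->bchw", dyv, self.W.value, optimize=True)


class Dropout:
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        self._mask = keep
        return x * keep

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam with bias correction; state keyed by parameter identity."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
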