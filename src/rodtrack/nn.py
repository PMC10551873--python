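"""Minimal CPU convolutional-network engine.

Implements exactly the layers a U-Net needs -- 2-D convolution (same
padding), 2x2 max pooling, 2x2-stride-2 transposed convolution, ReLU,
sigmoid -- with explicit reverse-mode gradients, plus the AMSgrad
optimizer and a pixelwise binary cross-entropy loss.

Convolutions are evaluated by lowering to matrix multiplication
(im2col), so the heavy lifting is a single BLAS GEMM per layer.  All
layers accept float32 (the training default) or float64 (used by the
finite-difference gradient checks in the test suite).

Arrays follow the (N, C, H, W) layout throughout.
"""

from __future__ import annotations

import ctypes

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Training allocates and frees hundreds of MB of im2col buffers per
# step; with glibc's default mmap threshold every step pays the page
# faults anew.  Raising the threshold keeps these blocks on the heap
# for reuse (several-fold step-time reduction on Linux; harmless no-op
# elsewhere).
try:  # M_MMAP_THRESHOLD = -3, M_TRIM_THRESHOLD = -1
    _libc = ctypes.CDLL("libc.so.6")
    _libc.mallopt(-3, 1 << 30)
    _libc.mallopt(-1, 1 << 30)
except (OSError, AttributeError):  # pragma: no cover
    pass

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "ReLU",
    "sigmoid",
    "bce_with_logits",
    "AMSgrad",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Conv2d:
    """k x k convolution with 'same' zero padding, stride 1.

    Weights are He-initialized (ReLU fan-in scaling) from the supplied
    generator; biases start at zero.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = self._im2col(x)
        y = cols @ self.w.value + self.b.value
        self._cache = (cols, (n, c, h, w))
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.c_out)
        self.w.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        # dx is the full correlation of dy with the flipped kernel, so it
        # lowers to the same im2col + GEMM as the forward pass.
        k = self.k
        wk = self.w.value.reshape(c, k, k, self.c_out)
        w_flip = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.c_out * k * k, c)
        p = (k - 1) // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(dyp, (k, k), axis=(2, 3))
        dcols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w,
                                                        self.c_out * k * k)
        dx = (dcols @ w_flip).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._cache = None
        return np.ascontiguousarray(dx)


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = c_in  # each output pixel sees exactly one input pixel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 2, 2))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # (N,H,W,O,2,2)
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        dyt = dy.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        # dyt: (N,H,W,O,2,2)
        self.w.grad += np.tensordot(x, dyt, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dyt, self.w.value, axes=([3, 4, 5], [1, 2, 3]))
        self._cache = None
        return dx.transpose(0, 3, 1, 2)


class MaxPool2d:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool input dims must be even, got {h}x{w}")
        xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xw = xw.reshape(n, c, h // 2, w // 2, 4)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxw = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
        dx = dxw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(n, c, h, w)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: np.ndarray):
    """Mean binary cross-entropy of sigmoid(z) against a {0,1} target.

    Fusing the sigmoid into the loss avoids overflow for large |z|.
    Returns (loss, dloss/dz).
    """
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - target) / z.size
    return float(loss), dz.astype(z.dtype)


class AMSgrad:
    """Adam with the non-decreasing second-moment estimate (AMSgrad).

    Uses the bias-corrected step size; the max-accumulator v_hat replaces
    v in the denominator, which removes Adam's occasional effective
    step-size growth.
    """

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.vhat = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v, vh in zip(self.params, self.m, self.v, self.vhat):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            np.maximum(vh, v, out=vh)
            p.value -= self.lr * (m / b1t) / (np.sqrt(vh / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
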