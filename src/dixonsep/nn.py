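"""Minimal NumPy CNN engine: conv / transposed-conv / PReLU layers with
hand-written backpropagation, He initialization and an Adam optimizer.

Only what the hierarchical water-fat network needs is implemented:
stride-1 'same' convolutions (feature extraction), kxk stride-k
convolutions (downsampling), kxk stride-k transposed convolutions
(upsampling), per-channel PReLU, channel concatenation and an l1 loss.
Tensors are (N, C, H, W) float32; all randomness flows through an
explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "PReLU",
    "Adam",
    "l1_loss",
]

_DT = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_DT)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    def params(self) -> list[Param]:
        return []


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols.reshape(n, c * k * k, ho * wo)


class Conv2d(Module):
    """2D convolution; He-normal initialized (std = sqrt(2 / fan_in))."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.weight = Param(rng.standard_normal((cout, cin * k * k)) * np.sqrt(2.0 / fan_in))
        self.bias = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        if k == 1 and s == 1:
            cols = np.ascontiguousarray(x).reshape(n, c, h * w)
            ho, wo = h, w
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
            cols = _im2col(xp, k, s)
            ho = (h + 2 * p - k) // s + 1
            wo = (w + 2 * p - k) // s + 1
        y = np.matmul(self.weight.value, cols) + self.bias.value[None, :, None]
        if train:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, self.cout, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "forward(train=True) must precede backward"
        n, _, ho, wo = dy.shape
        dyf = np.ascontiguousarray(dy).reshape(n, self.cout, ho * wo)
        self.weight.grad += np.matmul(dyf, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, dyf)
        nb, c, h, w = self._xshape
        p, k, s = self.pad, self.k, self.stride
        self._cols = None
        if k == 1 and s == 1:
            return dcols.reshape(nb, c, h, w)
        # col2im: scatter-add the 9 (or 4) kernel taps back onto the padded grid
        dxp = np.zeros((nb, c, h + 2 * p, w + 2 * p), dtype=_DT)
        dcols = dcols.reshape(nb, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvTranspose2d(Module):
    """Transposed convolution with kernel == stride (exact upsampling tiles)."""

    def __init__(self, cin: int, cout: int, k: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.cin, self.cout = k, cin, cout
        self.weight = Param(rng.standard_normal((cin, cout, k, k)) * np.sqrt(2.0 / cin))
        self.bias = Param(np.zeros(cout))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        y = np.empty((n, self.cout, h * k, w * k), dtype=_DT)
        for i in range(k):
            for j in range(k):
                y[:, :, i::k, j::k] = np.moveaxis(
                    np.tensordot(x, self.weight.value[:, :, i, j], axes=([1], [0])), 3, 1
                )
        y += self.bias.value[None, :, None, None]
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        k = self.k
        dx = np.zeros_like(self._x)
        for i in range(k):
            for j in range(k):
                part = dy[:, :, i::k, j::k]
                self.weight.grad[:, :, i, j] += np.tensordot(
                    self._x, part, axes=([0, 2, 3], [0, 2, 3])
                )
                dx += np.moveaxis(
                    np.tensordot(part, self.weight.value[:, :, i, j], axes=([1], [1])), 3, 1
                )
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        self._x = None
        return dx


class PReLU(Module):
    """Per-channel parametric ReLU, y = max(x, 0) + a * min(x, 0)."""

    def __init__(self, channels: int, init: float = 0.25):
        self.a = Param(np.full(channels, init))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.a]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        neg = np.minimum(x, 0)
        return np.maximum(x, 0) + self.a.value[None, :, None, None] * neg

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        neg = x < 0
        self.a.grad += np.where(neg, dy * x, 0).sum(axis=(0, 2, 3))
        dx = dy * np.where(neg, self.a.value[None, :, None, None], 1.0).astype(_DT)
        self._x = None
        return dx


class Adam:
    """Adam optimizer with bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = (np.sign(diff) / diff.size).astype(_DT)
    return loss, grad
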