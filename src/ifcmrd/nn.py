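"""Minimal CPU neural-network engine (float32 numpy, manual backprop).

Implements exactly the pieces the residual image classifier needs:
3x3/1x1/7x7 convolutions via im2col + BLAS matmul, ReLU, 2x2 max pooling,
global average pooling, dense layers, residual blocks with optional 1x1
projection shortcuts, softmax cross-entropy, and Adam.  Everything is
deterministic given the initialization/shuffle seeds — there is no
threading or nondeterministic reduction, which is what makes the
bit-reproducibility contract of training runs possible on CPU.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

try:  # numba accelerates the im2col/col2im memory shuffles ~3x
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def _im2col_kernel(xp, k, s, ho, wo, cols):  # pragma: no cover - jitted
    n, c, hp, wp = xp.shape
    for ni in range(n):
        for oy in range(ho):
            for ox in range(wo):
                row = (ni * ho + oy) * wo + ox
                col = 0
                for ci in range(c):
                    for i in range(k):
                        base_y = oy * s + i
                        for j in range(k):
                            cols[row, col] = xp[ni, ci, base_y, ox * s + j]
                            col += 1


@njit(cache=False)
def _col2im_kernel(dcols, k, s, ho, wo, dxp):  # pragma: no cover - jitted
    n, c, hp, wp = dxp.shape
    for ni in range(n):
        for oy in range(ho):
            for ox in range(wo):
                row = (ni * ho + oy) * wo + ox
                col = 0
                for ci in range(c):
                    for i in range(k):
                        base_y = oy * s + i
                        for j in range(k):
                            dxp[ni, ci, base_y, ox * s + j] += dcols[row, col]
                            col += 1


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (e.g. batch-norm running statistics); the
        returned arrays are mutated in place so references stay valid."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution, 'same'-style symmetric zero padding, square kernel."""

    def __init__(
        self,
        cin: int,
        cout: int,
        ksize: int = 3,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        self.cin, self.cout, self.k, self.stride = cin, cout, ksize, stride
        self.pad = (ksize - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.w = Param(rng.normal(0, std, (cin * ksize * ksize, cout)))
        self.b = Param(np.zeros(cout))
        self._cache: Optional[tuple] = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        return win

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.k
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, hp, wp = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        if _HAVE_NUMBA:
            cols = np.empty((n * ho * wo, c * k * k), dtype=np.float32)
            _im2col_kernel(xp, k, s, ho, wo, cols)
        else:
            win = self._im2col(xp)
            cols = np.ascontiguousarray(
                win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k),
                dtype=np.float32,
            )
        y = cols @ self.w.value + self.b.value
        if train:
            self._cache = (cols, x.shape, (n, ho, wo))
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, x_shape, (n, ho, wo) = self._cache
        gf = np.ascontiguousarray(
            g.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout), dtype=np.float32
        )
        self.w.grad += cols.T @ gf
        self.b.grad += gf.sum(axis=0)
        dcols = gf @ self.w.value.T
        p, s, k = self.pad, self.stride, self.k
        _, c, h, w = x_shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        if _HAVE_NUMBA:
            _col2im_kernel(dcols, k, s, ho, wo, dxp)
        else:
            dc = np.ascontiguousarray(
                dcols.reshape(n, ho, wo, self.cin, k, k).transpose(4, 5, 0, 3, 1, 2)
            )
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dc[i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training uses batch statistics and maintains running estimates
    (momentum 0.9) that the evaluation path uses, so inference on a
    single cell is independent of its batch companions.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean *= m
            self.running_mean += (1 - m) * mu
            self.running_var *= m
            self.running_var += (1 - m) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
            self._xhat, self._inv = xhat, inv
            return (
                self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]
            ).astype(np.float32)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.value * inv)[None, :, None, None]
        shift = (self.beta.value - self.gamma.value * self.running_mean * inv)[
            None, :, None, None
        ]
        return (x * scale + shift).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        axes = (0, 2, 3)
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        n = g.shape[0] * g.shape[2] * g.shape[3]
        g_mean = g.mean(axis=axes)
        gx_mean = (g * xhat).mean(axis=axes)
        dx = (self.gamma.value * inv)[None, :, None, None] * (
            g
            - g_mean[None, :, None, None]
            - xhat * gx_mean[None, :, None, None]
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even input sides only)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = np.ascontiguousarray(
            x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = xr.argmax(axis=4)
            self._shape = x.shape
            return np.take_along_axis(xr, self._argmax[..., None], axis=4)[..., 0]
        return xr.max(axis=4)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._argmax[..., None], g[..., None], axis=4)
        return np.ascontiguousarray(
            out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            (g / (h * w))[:, :, None, None], self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(
        self,
        cin: int,
        cout: int,
        rng: Optional[np.random.Generator] = None,
        std: Optional[float] = None,
    ):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin) if std is None else std
        self.w = Param(rng.normal(0, std, (cin, cout)))
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return (g @ self.w.value.T).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Residual(Layer):
    """y = body(x) + shortcut(x); shortcut is identity or a 1x1 projection."""

    def __init__(self, body: Sequential, projection: Optional[Layer] = None):
        self.body = body
        self.projection = projection

    def params(self) -> list[Param]:
        ps = self.body.params()
        if self.projection is not None:
            ps += self.projection.params()
        return ps

    def buffers(self) -> list[np.ndarray]:
        bs = self.body.buffers()
        if self.projection is not None:
            bs += self.projection.buffers()
        return bs

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skip = x if self.projection is None else self.projection.forward(x, train)
        return self.body.forward(x, train) + skip

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = self.body.backward(g)
        if self.projection is None:
            return gx + g
        return gx + self.projection.backward(g)


# ---------------------------------------------------------------------------
# Loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def get_weights(params: Sequence[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_weights(params: Sequence[Param], weights: Sequence[np.ndarray]) -> None:
    for p, w in zip(params, weights):
        p.value[...] = w


def get_state(
    params: Sequence[Param], buffers: Sequence[np.ndarray]
) -> list[np.ndarray]:
    """Snapshot trained weights plus non-trained buffers (running stats)."""
    return [p.value.copy() for p in params] + [b.copy() for b in buffers]


def set_state(
    params: Sequence[Param],
    buffers: Sequence[np.ndarray],
    state: Sequence[np.ndarray],
) -> None:
    n = len(params)
    for p, w in zip(params, state[:n]):
        p.value[...] = w
    for b, w in zip(buffers, state[n:]):
        b[...] = w


# ---------------------------------------------------------------------------
# Plateau tracking (LR schedule / early stopping)


class PlateauTracker:
    """Counts consecutive epochs without validation-loss improvement.

    'Improvement' means a strict decrease below the best seen loss by more
    than ``tol`` (guards against float jitter resetting patience).
    ``update`` returns True on the epoch at which the non-improvement
    streak reaches ``patience``; for the LR schedule the streak counter is
    then reset (``reset_on_trigger=True``) so reductions can recur.
    """

    def __init__(self, patience: int, tol: float = 1e-4, reset_on_trigger: bool = False):
        self.patience = patience
        self.tol = tol
        self.reset_on_trigger = reset_on_trigger
        self.best = np.inf
        self.wait = 0

    def update(self, loss: float) -> bool:
        if loss < self.best - self.tol:
            self.best = loss
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            if self.reset_on_trigger:
                self.wait = 0
            return True
        return False
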