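"""Layers with explicit backward passes on (C, D, H, W) float32 tensors.

Convolutions use im2col + GEMM; the input gradient of a stride-1
same-padded convolution is computed as a convolution of the output
gradient with the spatially flipped, channel-transposed kernels, which
keeps everything inside matrix multiplies.
"""

from __future__ import annotations

import numpy as np

from deshkit.nn._kernels import HAVE_NUMBA, conv3d_forward, conv3d_weight_grad

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "UpConv3d",
    "Linear",
    "SqueezeExcite",
    "ConvBlock",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _zero_pad(x: np.ndarray, p: int) -> np.ndarray:
    """Fast zero padding of the three spatial axes (np.pad is slow here)."""
    c, d, h, w = x.shape
    out = np.zeros((c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=np.float32)
    out[:, p : p + d, p : p + h, p : p + w] = x
    return out


class Conv3d(Layer):
    """Stride-1 3D convolution with 'same' zero padding (odd kernels).

    Evaluated as k^3 shifted flat GEMMs over the zero-padded input: for a
    kept output voxel the flat padded index arithmetic is exact, and the
    border ring of the padded frame (where flat shifts wrap rows) is
    cropped away, so no im2col gather is needed.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, k, k, k, c_out))
        self.w = Param("conv_w", w)
        self.b = Param("conv_b", np.zeros(c_out))
        self._xp: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _offsets(self, hp: int, wp: int):
        k = self.k
        for od in range(k):
            for oh in range(k):
                for ow in range(k):
                    yield od, oh, ow, od * hp * wp + oh * wp + ow

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        d, h, w = x.shape[1:]
        p = self.pad
        xp = _zero_pad(x.astype(np.float32, copy=False), p)
        self._xp = xp if self.train_mode else None
        if HAVE_NUMBA:
            y = np.empty((self.c_out, d, h, w), dtype=np.float32)
            conv3d_forward(xp, self.w.value, y)
        else:
            y = self._forward_gemm(xp, self.w.value, (d, h, w))
        return y + self.b.value[:, None, None, None]

    @staticmethod
    def _forward_gemm(xp: np.ndarray, wv: np.ndarray, out_shape) -> np.ndarray:
        c_in, k, f_out = wv.shape[0], wv.shape[1], wv.shape[4]
        d, h, w = out_shape
        dp, hp, wp = xp.shape[1:]
        npad = dp * hp * wp
        flat = xp.reshape(c_in, npad)
        y = np.zeros((f_out, npad), dtype=np.float32)
        for od in range(k):
            for oh in range(k):
                for ow in range(k):
                    s = od * hp * wp + oh * wp + ow
                    wo = np.ascontiguousarray(wv[:, od, oh, ow, :].T)
                    seg = flat[:, s:] if s else flat
                    y[:, : npad - s] += wo @ seg
        return y.reshape(f_out, dp, hp, wp)[:, :d, :h, :w].copy()

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward before forward (or eval mode)")
        xp = self._xp
        self._xp = None
        c, d, h, w = self._shape
        p = self.pad
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.b.grad += dy.sum(axis=(1, 2, 3))
        # input gradient: same-padded convolution of dy with flipped,
        # channel-transposed kernels
        wt = np.ascontiguousarray(
            self.w.value[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0)
        )
        dyp = _zero_pad(dy, p)
        if HAVE_NUMBA:
            conv3d_weight_grad(xp, dy, self.w.grad)
            dx = np.empty((self.c_in, d, h, w), dtype=np.float32)
            conv3d_forward(dyp, wt, dx)
        else:
            self.w.grad += self._weight_grad_gemm(xp, dy)
            dx = self._forward_gemm(dyp, wt, (d, h, w))
        return dx

    @staticmethod
    def _weight_grad_gemm(xp: np.ndarray, dy: np.ndarray) -> np.ndarray:
        c_in = xp.shape[0]
        f_out, d, h, w = dy.shape
        dp, hp, wp = xp.shape[1:]
        k = dp - d + 1
        npad = dp * hp * wp
        flat = xp.reshape(c_in, npad)
        dyp = np.zeros((f_out, dp, hp, wp), dtype=np.float32)
        dyp[:, :d, :h, :w] = dy
        dyf = dyp.reshape(f_out, npad)
        dw = np.zeros((c_in, k, k, k, f_out), dtype=np.float32)
        for od in range(k):
            for oh in range(k):
                for ow in range(k):
                    s = od * hp * wp + oh * wp + ow
                    seg = flat[:, s:] if s else flat
                    dw[:, od, oh, ow, :] = seg @ dyf[:, : npad - s].T
        return dw


class BatchNorm3d(Layer):
    """Per-channel normalisation over the spatial grid (batch of one).

    With a batch of one this is instance normalisation, and the same
    per-input statistics are used at inference: the network co-adapts to
    per-subject statistics during training, so an exponential moving
    average over subjects matches none of them (eval-mode collapse).
    Inference stays deterministic — the statistics are a pure function of
    the input.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.c = c
        self.eps = eps
        self.gamma = Param("bn_gamma", np.ones(c))
        self.beta = Param("bn_beta", np.zeros(c))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3))
        var = x.var(axis=(1, 2, 3))
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        if self.train_mode:
            self._cache = (xhat, inv)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = float(np.prod(dy.shape[1:]))
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None, None]
        s1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (inv[:, None, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 (grid must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"grid {x.shape[1:]} not divisible by 2 for pooling")
        win = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        win = win.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = win.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        win = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(win, self._arg[..., None], dy[..., None], axis=-1)
        win = win.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return win.reshape(c, d, h, w)


class UpConv3d(Layer):
    """Up-convolution: 2x zero-stuffed upsampling followed by a k=3 conv.

    Equivalent to a stride-2 transposed convolution with kernel 3 that
    exactly doubles each grid axis.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.conv = Conv3d(c_in, c_out, k=3, rng=rng)

    def params(self) -> list[Param]:
        return self.conv.params()

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        self.conv.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        stuffed = np.zeros((c, 2 * d, 2 * h, 2 * w), dtype=np.float32)
        stuffed[:, ::2, ::2, ::2] = x
        return self.conv.forward(stuffed)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dstuffed = self.conv.backward(dy)
        return dstuffed[:, ::2, ::2, ::2]


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Param("lin_w", w)
        self.b = Param("lin_b", np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += np.outer(self._x, dy)
        self.b.grad += dy
        return dy @ self.w.value.T


class SqueezeExcite(Layer):
    """Channel self-attention: squeeze (GAP) -> two-layer gate -> rescale."""

    def __init__(self, c: int, reduction: int = 4, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, c // reduction)
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x.mean(axis=(1, 2, 3))
        h = self.fc1.forward(z)
        self._hmask = h > 0
        h = h * self._hmask
        a = self.fc2.forward(h)
        s = 1.0 / (1.0 + np.exp(-a))
        self._s = s
        return x * s[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        ds = (dy * x).sum(axis=(1, 2, 3))
        da = ds * s * (1.0 - s)
        dh = self.fc2.backward(da) * self._hmask
        dz = self.fc1.backward(dh)
        n = float(np.prod(x.shape[1:]))
        dx = dy * s[:, None, None, None]
        dx += dz[:, None, None, None] / n
        return dx


class ConvBlock(Layer):
    """conv(3,3,3) + batch norm + ReLU, optionally followed by attention."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 attention: bool = False):
        self.layers: list[Layer] = [Conv3d(c_in, c_out, 3, rng=rng), BatchNorm3d(c_out), ReLU()]
        if attention:
            self.layers.append(SqueezeExcite(c_out, rng=rng))

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        for l in self.layers:
            l.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
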