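"""Minimal 3-D neural-network engine (numpy, channels-last, hand-written backprop).

Everything here operates on float32 arrays of shape (N, D, H, W, C).
Convolutions use TF-style "same" padding with ceil division at strided
layers, which yields the 70 -> 35 -> 18 -> 9 -> 5 -> 3 spatial trace of the
perfusion networks.  Each layer caches what its backward pass needs; calling
``backward`` immediately after ``forward`` on the same batch is the contract.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "GroupNorm",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool",
    "Dropout",
    "Dense",
    "AdamW",
    "softmax",
]

_DT = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)


def _same_pad(n_in: int, k: int, s: int) -> tuple[int, int, int]:
    """TF 'same' padding: out = ceil(n/s); returns (out, pad_before, pad_after)."""
    out = -(-n_in // s)
    pad = max((out - 1) * s + k - n_in, 0)
    before = pad // 2
    return out, before, pad - before


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    train_mode_sensitive = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3-D convolution, 'same' ceil padding, via im2col + one matmul.

    Column layout is (c_in, kz, ky, kx): the order a strided window view of
    a channels-last array flattens to.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        fan_in = kernel ** 3 * c_in
        if zero_init:
            w = np.zeros((fan_in, c_out))
        else:
            rng = rng or np.random.default_rng()
            # He-style init for ReLU trunks
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        n, d, h, w_, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv3d expected {self.c_in} channels, got {c}")
        k, s = self.k, self.stride
        od, pd0, pd1 = _same_pad(d, k, s)
        oh, ph0, ph1 = _same_pad(h, k, s)
        ow, pw0, pw1 = _same_pad(w_, k, s)
        xp = np.pad(x, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(
            xp, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
        cols = view.reshape(n, od, oh, ow, c * k ** 3)
        out = cols.reshape(-1, cols.shape[-1]) @ self.w.value + self.b.value
        self._cache = (cols, xp.shape, (pd0, ph0, pw0), x.shape)
        return out.reshape(n, od, oh, ow, self.c_out)

    def backward(self, dout, need_input: bool = True):
        cols, xp_shape, (pd0, ph0, pw0), x_shape = self._cache
        n, od, oh, ow, co = dout.shape
        dflat = dout.reshape(-1, co)
        self.w.grad += cols.reshape(-1, cols.shape[-1]).T @ dflat
        self.b.grad += dflat.sum(axis=0)
        self._cache = None
        if not need_input:
            return None
        k, s, ci = self.k, self.stride, self.c_in
        dcols = (dflat @ self.w.value.T).reshape(n, od, oh, ow, ci, k, k, k)
        dxp = np.zeros(xp_shape, dtype=_DT)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, dz:dz + od * s:s, dy:dy + oh * s:s,
                        dx:dx + ow * s:s, :] += dcols[..., dz, dy, dx]
        _, d, h, w_, _ = x_shape
        return dxp[:, pd0:pd0 + d, ph0:ph0 + h, pw0:pw0 + w_, :]


class GroupNorm(Layer):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError(f"norm groups {groups} must divide channel width {channels}")
        self.g, self.c, self.eps = groups, channels, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        n = x.shape[0]
        spatial = x.shape[1:-1]
        cg = self.c // self.g
        xg = x.reshape(n, -1, self.g, cg)            # (N, S, g, c/g)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mu) * inv
        self._cache = (xhat, inv, n, spatial, cg)
        out = xhat.reshape(n, *spatial, self.c) * self.gamma.value + self.beta.value
        return out.astype(_DT, copy=False)

    def backward(self, dout):
        xhat, inv, n, spatial, cg = self._cache
        xhat_full = xhat.reshape(n, *spatial, self.c)
        self.gamma.grad += (dout * xhat_full).reshape(-1, self.c).sum(axis=0)
        self.beta.grad += dout.reshape(-1, self.c).sum(axis=0)
        dxhat = (dout * self.gamma.value).reshape(n, -1, self.g, cg)
        m = dxhat.shape[1] * cg
        s1 = dxhat.sum(axis=(1, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 3), keepdims=True)
        dxg = inv / m * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dxg.reshape(n, *spatial, self.c).astype(_DT, copy=False)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_DT, copy=False)

    def backward(self, dout):
        return np.where(self._mask, dout, 0).astype(_DT, copy=False)


class MaxPool3d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2):
        self.k, self.stride = kernel, stride

    def forward(self, x, train=False, rng=None):
        n, d, h, w_, c = x.shape
        k, s = self.k, self.stride
        od, pd0, pd1 = _same_pad(d, k, s)
        oh, ph0, ph1 = _same_pad(h, k, s)
        ow, pw0, pw1 = _same_pad(w_, k, s)
        xp = np.pad(x, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)),
                    constant_values=-np.inf)
        best = np.full((n, od, oh, ow, c), -np.inf, dtype=_DT)
        arg = np.zeros((n, od, oh, ow, c), dtype=np.int8)
        i = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    win = xp[:, dz:dz + od * s:s, dy:dy + oh * s:s, dx:dx + ow * s:s, :]
                    upd = win > best
                    best = np.where(upd, win, best)
                    arg = np.where(upd, np.int8(i), arg)
                    i += 1
        self._cache = (arg, xp.shape, (pd0, ph0, pw0), x.shape)
        return best

    def backward(self, dout):
        arg, xp_shape, (pd0, ph0, pw0), x_shape = self._cache
        n, od, oh, ow, c = dout.shape
        k, s = self.k, self.stride
        dxp = np.zeros(xp_shape, dtype=_DT)
        i = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, dz:dz + od * s:s, dy:dy + oh * s:s, dx:dx + ow * s:s, :] += \
                        np.where(arg == i, dout, 0)
                    i += 1
        _, d, h, w_, _ = x_shape
        self._cache = None
        return dxp[:, pd0:pd0 + d, ph0:ph0 + h, pw0:pw0 + w_, :]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        n, d, h, w_, c = self._shape
        scale = 1.0 / (d * h * w_)
        return np.broadcast_to(
            dout[:, None, None, None, :] * scale, self._shape).astype(_DT)


class Dropout(Layer):
    train_mode_sensitive = True

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            rng = rng or np.random.default_rng()
            lim = np.sqrt(6.0 / (n_in + n_out))   # Glorot uniform
            w = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.w = Param(w)
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t / (np.sqrt(v / b2t) + self.eps)
                                  + self.wd * p.value)
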