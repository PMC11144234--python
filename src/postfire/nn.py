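"""Minimal NumPy neural-network core with manual backpropagation.

The networks in this package are deliberately CPU-sized (dense encoders of a
few thousand weights, 32x32 convolutional generators), so they are built on
a small layer library rather than a GPU framework: every layer implements
``forward``/``backward`` explicitly, all randomness flows through
``numpy.random.Generator`` objects, and a fixed seed therefore yields a
bitwise-identical loss trajectory on a given machine.

Conventions: dense activations are ``(batch, features)``; image activations
are ``(batch, channels, height, width)``.  Convolutions use im2col;
gradients accumulate into ``Param.grad`` and are consumed by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------- dense ----

class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))  # Glorot
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


# ----------------------------------------------------------- activations ----

class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return np.where(self._m, x, 0.0)

    def backward(self, dy):
        return np.where(self._m, dy, 0.0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._m = x > 0
        return np.where(self._m, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._m, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; identity when ``train=False`` or rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------- conv -----

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,C,H,W) -> columns (B, oh*ow, C*k*k) plus output spatial shape."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # B,C,H',W',k,k
    win = win[:, :, ::stride, ::stride]
    b, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), (oh, ow)


class Conv2d(Layer):
    """Stride-s convolution via im2col; kernel init N(0, 0.02)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.W = Param(rng.normal(0.0, 0.02, size=(c_in * k * k, c_out)))
        self.b = Param(np.zeros(c_out))
        self._scatter_cache: dict[tuple, np.ndarray] = {}

    def params(self):
        return [self.W, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def forward(self, x, train=True):
        self._xshape = x.shape
        cols, (oh, ow) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        y = cols @ self.W.value + self.b.value  # (B, L, c_out)
        self._out_hw = (oh, ow)
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, oh, ow)

    def _scatter_index(self, h: int, w: int) -> np.ndarray:
        """Flat indices into the padded image for each im2col column entry."""
        key = (h, w)
        idx = self._scatter_cache.get(key)
        if idx is not None:
            return idx
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        oh, ow = self.out_shape(h, w)
        base = np.arange(self.c_in)[:, None, None] * (hp * wp)
        ki, kj = np.meshgrid(np.arange(self.k), np.arange(self.k), indexing="ij")
        patch = base + ki[None] * wp + kj[None]            # (C,k,k)
        oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        origin = (oi * self.stride)[..., None] * wp + (oj * self.stride)[..., None]
        # (oh,ow,1,1,1) + (1,1,C,k,k) -> (L, C*k*k)
        idx = (origin.reshape(oh * ow, 1, 1, 1) + patch[None]).reshape(oh * ow, -1)
        self._scatter_cache[key] = idx
        return idx

    def backward(self, dy):
        b, _, oh, ow = dy.shape
        dy2 = dy.reshape(b, self.c_out, oh * ow).transpose(0, 2, 1)  # (B,L,c_out)
        self.W.grad += np.einsum("blk,blo->ko", self._cols, dy2)
        self.b.grad += dy2.sum(axis=(0, 1))
        dcols = dy2 @ self.W.value.T                                  # (B,L,C*k*k)
        h, w = self._xshape[2:]
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        idx = self._scatter_index(h, w)
        dxp = np.zeros((b, self.c_in * hp * wp))
        np.add.at(dxp, (slice(None), idx.ravel()),
                  dcols.reshape(b, -1))
        dxp = dxp.reshape(b, self.c_in, hp, wp)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ------------------------------------------------------------- norms -------

class _NormBase(Layer):
    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _normalize(self, x, axes):
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        self._axes = axes
        self._n = x.size / mu.size
        g = self.gamma.value.reshape(1, -1, 1, 1)
        b = self.beta.value.reshape(1, -1, 1, 1)
        return self._xhat * g + b

    def backward(self, dy):
        g = self.gamma.value.reshape(1, -1, 1, 1)
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        n, axes = self._n, self._axes
        return (self._inv / n) * (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        )


class BatchNorm2d(_NormBase):
    """Batch statistics over (batch, H, W); running stats for inference."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(c, eps)
        self.momentum = momentum
        self.run_mu = np.zeros(c)
        self.run_var = np.ones(c)

    def forward(self, x, train=True):
        if train:
            m = x.mean(axis=(0, 2, 3))
            v = x.var(axis=(0, 2, 3))
            self.run_mu = (1 - self.momentum) * self.run_mu + self.momentum * m
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * v
            return self._normalize(x, (0, 2, 3))
        g = self.gamma.value.reshape(1, -1, 1, 1)
        b = self.beta.value.reshape(1, -1, 1, 1)
        mu = self.run_mu.reshape(1, -1, 1, 1)
        sd = np.sqrt(self.run_var + self.eps).reshape(1, -1, 1, 1)
        return (x - mu) / sd * g + b


class InstanceNorm2d(_NormBase):
    """Per-sample per-channel normalization over the spatial grid."""

    def forward(self, x, train=True):
        return self._normalize(x, (2, 3))


# ------------------------------------------------------- self-attention ----

class SelfAttention2d(Layer):
    """Gated-residual self-attention over spatial positions.

    Queries/keys use a channel bottleneck C//8; the residual gate gamma is
    initialized at 0 so the block is the identity at the start of training.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        cf = max(1, c // 8)
        self.Wf = Param(rng.normal(0.0, 0.02, size=(cf, c)))
        self.Wg = Param(rng.normal(0.0, 0.02, size=(cf, c)))
        self.Wh = Param(rng.normal(0.0, 0.02, size=(c, c)))
        self.gamma = Param(np.zeros(1))

    def params(self):
        return [self.Wf, self.Wg, self.Wh, self.gamma]

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        self._shape = x.shape
        xf = x.reshape(b, c, h * w)
        self._x = xf
        f = np.einsum("fc,bcn->bfn", self.Wf.value, xf)
        g = np.einsum("fc,bcn->bfn", self.Wg.value, xf)
        hh = np.einsum("oc,bcn->bon", self.Wh.value, xf)
        s = np.einsum("bfi,bfj->bij", f, g)          # s[i,j] = f_i . g_j
        s = s - s.max(axis=2, keepdims=True)
        a = np.exp(s)
        a /= a.sum(axis=2, keepdims=True)            # attend over j
        o = np.einsum("bij,bcj->bci", a, hh)
        self._f, self._g, self._h, self._a, self._o = f, g, hh, a, o
        y = xf + self.gamma.value[0] * o
        return y.reshape(b, c, h, w)

    def backward(self, dy):
        b, c, h, w = self._shape
        dyf = dy.reshape(b, c, h * w)
        self.gamma.grad += np.array([(dyf * self._o).sum()])
        do = self.gamma.value[0] * dyf
        da = np.einsum("bci,bcj->bij", do, self._h)
        dh = np.einsum("bij,bci->bcj", self._a, do)
        ds = self._a * (da - (da * self._a).sum(axis=2, keepdims=True))
        df = np.einsum("bij,bfj->bfi", ds, self._g)
        dg = np.einsum("bij,bfi->bfj", ds, self._f)
        x = self._x
        self.Wf.grad += np.einsum("bfn,bcn->fc", df, x)
        self.Wg.grad += np.einsum("bfn,bcn->fc", dg, x)
        self.Wh.grad += np.einsum("bon,bcn->oc", dh, x)
        dx = dyf.copy()
        dx += np.einsum("fc,bfn->bcn", self.Wf.value, df)
        dx += np.einsum("fc,bfn->bcn", self.Wg.value, dg)
        dx += np.einsum("oc,bon->bcn", self.Wh.value, dh)
        return dx.reshape(b, c, h, w)


# ---------------------------------------------------------------- optim ----

class Adam:
    """Adam with optional L2 weight decay on a designated parameter subset."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_params: list[Param] | None = None):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decay_set = set(map(id, decay_params or []))
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and id(p) in self.decay_set:
                g = g + 2.0 * self.weight_decay * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------- losses ---

def mse_loss(y_hat: np.ndarray, y: np.ndarray):
    diff = y_hat - y
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def l1_loss(y_hat: np.ndarray, y: np.ndarray):
    diff = y_hat - y
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def bce_with_logits(z: np.ndarray, target: float):
    """Stable binary cross-entropy against a constant 0/1 target."""
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return float(loss.mean()), (sig - target) / z.size


def l2_penalty(params: list[Param]) -> float:
    return float(sum(np.sum(p.value**2) for p in params))
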