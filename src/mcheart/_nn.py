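"""Minimal CPU neural-network layer library (numpy, explicit backprop).

Supplies exactly the pieces the murmur classifier needs: same-padding 2-D
convolution, max-feature-map, 2x2 max pooling, batch normalization, Swish
with a trainable slope, dense layers, scaled dot-product multi-head
self-attention, and Adam. Every layer caches its forward inputs and
implements an analytic backward pass; the gradients are verified against
finite differences in the test suite.

Array conventions: feature maps are ``(N, C, H, W)``; sequences are
``(N, T, D)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "MFM",
    "MaxPool2",
    "BatchNorm2d",
    "Swish",
    "ReLULayer",
    "Identity",
    "Dense",
    "MultiHeadSelfAttention",
    "ToFrames",
    "MeanPoolTime",
    "ResidualBlock",
    "softmax",
    "weighted_cross_entropy",
    "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> dict[str, Param]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for i, layer in enumerate(self.layers):
            for k, p in layer.params().items():
                out[f"{i}.{k}"] = p
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Conv2d(Layer):
    """Same-padding, stride-1 convolution implemented as k*k shifted matmuls."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(1.0 / (in_ch * k * k))
        self.k = k
        self.w = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, self.w.value.shape[0], h, w))
        for i in range(self.k):
            for j in range(self.k):
                out += np.einsum(
                    "oc,nchw->nohw",
                    self.w.value[:, :, i, j],
                    xp[:, :, i : i + h, j : j + w],
                    optimize=True,
                )
        self._xp, self._shape = xp, (h, w)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        h, w = self._shape
        p = self.k // 2
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                patch = self._xp[:, :, i : i + h, j : j + w]
                self.w.grad[:, :, i, j] += np.einsum(
                    "nohw,nchw->oc", dout, patch, optimize=True
                )
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "oc,nohw->nchw", self.w.value[:, :, i, j], dout, optimize=True
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class MFM(Layer):
    """Max-feature-map: elementwise max over paired channel halves.

    2f input channels become f output channels; the gradient routes to the
    winning half (ties go to the first half).
    """

    def forward(self, x, train=False):
        c = x.shape[1]
        if c % 2:
            raise ValueError(f"MFM needs an even channel count, got {c}")
        a, b = x[:, : c // 2], x[:, c // 2 :]
        self._first_wins = a >= b
        return np.where(self._first_wins, a, b)

    def backward(self, dout):
        return np.concatenate(
            [dout * self._first_wins, dout * ~self._first_wins], axis=1
        )


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = (
            x[:, :, : 2 * h2, : 2 * w2]
            .reshape(n, c, h2, 2, w2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2, w2, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._in_shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dflat.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xc = x - mean[None, :, None, None]
        self._xhat = self._xc / self._std
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout):
        self.gamma.grad += (dout * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self._train:
            return dxhat / self._std
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dvar = (dxhat * self._xc).sum(axis=(0, 2, 3))[None, :, None, None] * (
            -0.5
        ) / self._std**3
        dmean = (-dxhat / self._std).sum(axis=(0, 2, 3))[None, :, None, None] + dvar * (
            -2.0 * self._xc.sum(axis=(0, 2, 3))[None, :, None, None] / m
        )
        return dxhat / self._std + dvar * 2.0 * self._xc / m + dmean / m


class Swish(Layer):
    """x * sigmoid(beta * x) with a trainable scalar slope beta."""

    def __init__(self, beta: float = 1.0):
        self.beta = Param(np.array(float(beta)))

    def params(self):
        return {"beta": self.beta}

    def forward(self, x, train=False):
        self._x = x
        self._s = sigmoid(self.beta.value * x)
        return x * self._s

    def backward(self, dout):
        x, s = self._x, self._s
        sp = s * (1.0 - s)
        self.beta.grad += float((dout * x * x * sp).sum())
        return dout * (s + x * self.beta.value * sp)


class ReLULayer(Layer):
    def forward(self, x, train=False):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dout):
        return dout * self._pos


class Identity(Layer):
    def forward(self, x, train=False):
        return x

    def backward(self, dout):
        return dout


class Dense(Layer):
    """Affine map on the last axis (any number of leading axes)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / in_dim)
        self.w = Param(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.w.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.w.value.T


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention; query, key, and value are the same
    input sequence, split over ``heads``, concatenated, and projected."""

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        if d_model % heads:
            raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
        self.h = heads
        self.dh = d_model // heads
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)

    def params(self):
        out = {}
        for name, lin in (("q", self.wq), ("k", self.wk), ("v", self.wv), ("o", self.wo)):
            for k, p in lin.params().items():
                out[f"w{name}.{k}"] = p
        return out

    def _split(self, x):  # (N,T,D) -> (N,h,T,dh)
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    @staticmethod
    def _merge(x):  # (N,h,T,dh) -> (N,T,D)
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x, train=False):
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=-1, keepdims=True)
        self._q, self._k, self._v, self._a = q, k, v, a
        return self.wo.forward(self._merge(a @ v))

    def backward(self, dout):
        d_ctx = self._split(self.wo.backward(dout))
        da = d_ctx @ self._v.transpose(0, 1, 3, 2)
        dv = self._a.transpose(0, 1, 3, 2) @ d_ctx
        ds = self._a * (da - (da * self._a).sum(axis=-1, keepdims=True))
        dq = ds @ self._k / np.sqrt(self.dh)
        dk = ds.transpose(0, 1, 3, 2) @ self._q / np.sqrt(self.dh)
        dx = self.wq.backward(self._merge(dq))
        dx += self.wk.backward(self._merge(dk))
        dx += self.wv.backward(self._merge(dv))
        return dx


class ToFrames(Layer):
    """(N, C, H, W) -> (N, W, C*H): one embedding per time frame."""

    def forward(self, x, train=False):
        self._shape = x.shape
        n, c, h, w = x.shape
        return x.transpose(0, 3, 1, 2).reshape(n, w, c * h)

    def backward(self, dout):
        n, c, h, w = self._shape
        return dout.reshape(n, w, c, h).transpose(0, 2, 3, 1)


class MeanPoolTime(Layer):
    """(N, T, D) -> (N, D)."""

    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._t, axis=1) / self._t


class ResidualBlock(Layer):
    """x + F(x) with an optional shape-matching skip path.

    The skip applies 2x2 max pooling when the main path halves the spatial
    dims and a 1x1 convolution when it changes the channel count; with
    matching shapes the skip is the identity, so a zeroed main path makes
    the block the identity map (up to its ``post`` activation).
    """

    def __init__(self, main: Sequential, skip_pools: int = 0,
                 skip_conv: Conv2d | None = None, post: Layer | None = None):
        self.main = main
        self.skip_pools = [MaxPool2() for _ in range(skip_pools)]
        self.skip_conv = skip_conv
        self.post = post if post is not None else Identity()

    def params(self):
        out = {f"main.{k}": p for k, p in self.main.params().items()}
        if self.skip_conv is not None:
            out.update({f"skip.{k}": p for k, p in self.skip_conv.params().items()})
        out.update({f"post.{k}": p for k, p in self.post.params().items()})
        return out

    def forward(self, x, train=False):
        fx = self.main.forward(x, train)
        sx = x
        for pool in self.skip_pools:
            sx = pool.forward(sx, train)
        if self.skip_conv is not None:
            sx = self.skip_conv.forward(sx, train)
        if fx.shape != sx.shape:
            raise ValueError(f"irreconcilable shapes {fx.shape} vs {sx.shape}")
        return self.post.forward(fx + sx, train)

    def backward(self, dout):
        d = self.post.backward(dout)
        dmain = self.main.backward(d)
        dskip = d
        if self.skip_conv is not None:
            dskip = self.skip_conv.backward(dskip)
        for pool in reversed(self.skip_pools):
            dskip = pool.backward(dskip)
        return dmain + dskip


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted categorical cross-entropy on (possibly soft) targets.

    Returns ``(loss, dloss/dlogits)``. With one-hot targets, a sample of
    class c contributes ``class_weights[c]`` times its unweighted loss.
    """
    n = logits.shape[0]
    p = softmax(logits)
    wy = targets * class_weights[None, :]
    loss = float(-(wy * np.log(np.maximum(p, 1e-12))).sum() / n)
    dlogits = (p * wy.sum(axis=1, keepdims=True) - wy) / n
    return loss, dlogits


class Adam:
    def __init__(self, params: dict[str, Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = np.zeros_like(p.value)

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
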