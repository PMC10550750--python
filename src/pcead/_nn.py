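"""Minimal reverse-mode autodiff for small convolutional networks.

Only the primitives the progressive GAN needs: 2-D convolution (im2col),
leaky ReLU, sigmoid, 2x2 average pooling, 2x nearest-neighbor upsampling,
dense layers, elementwise arithmetic and reductions, plus Adam.  Arrays
are NCHW float32; everything is plain NumPy so runs are deterministic on
a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "conv2d", "dense", "leaky_relu",
           "sigmoid", "avg_pool2", "upsample_nearest2", "mean_abs",
           "mean_square", "he_conv", "he_dense"]


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # graph-building arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data - other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.data.shape))

        out._backward = bwd
        return out

    def scale(self, s: float):
        out = Tensor(self.data * s, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s)

        out._backward = bwd
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def blend(a: Tensor, b: Tensor, alpha: float) -> Tensor:
    """(1 - alpha) * a + alpha * b — the fade-in combination."""
    return a.scale(1.0 - alpha) + b.scale(alpha)


# -- convolution -----------------------------------------------------------

def _im2col(x, k, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(cols, x_shape, k, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    xp = np.zeros((n, c, hp, wp), dtype=np.float32)
    cols = cols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution; w is (Cout, Cin, k, k)."""
    n, cin, h, wd = x.data.shape
    cout, _, k, _ = w.data.shape
    pad = k // 2
    cols = _im2col(x.data, k, pad)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T + b.data
    out = out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)
    res = Tensor(out, (x, w, b))

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            x._accumulate(_col2im(gmat @ wmat, x.data.shape, k, pad))

    res._backward = bwd
    return res


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (n, d) -> (n, m); w: (m, d)."""
    out = Tensor(x.data @ w.data.T + b.data, (x, w, b))

    def bwd(g):
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ w.data)

    out._backward = bwd
    return out


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    out = Tensor(x.data.reshape(n, -1), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    out._backward = bwd
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.where(mask, g, slope * g))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    pooled = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(pooled, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

    out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    up = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(up, (x,))

    def bwd(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def mean_abs(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data).mean(), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * np.sign(x.data) / x.data.size)

    out._backward = bwd
    return out


def mean_square(x: Tensor) -> Tensor:
    out = Tensor((x.data ** 2).mean(), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * 2.0 * x.data / x.data.size)

    out._backward = bwd
    return out


def he_conv(rng, cout, cin, k):
    std = np.sqrt(2.0 / (cin * k * k))
    return (Parameter(rng.normal(0, std, (cout, cin, k, k)).astype(np.float32)),
            Parameter(np.zeros(cout, dtype=np.float32)))


def he_dense(rng, m, d):
    std = np.sqrt(2.0 / d)
    return (Parameter(rng.normal(0, std, (m, d)).astype(np.float32)),
            Parameter(np.zeros(m, dtype=np.float32)))


class Adam:
    """Adam with per-parameter state; step() consumes and clears grads."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None

    def zero_grad(self):
        for p in self.params:
            p.grad = None
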