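"""Minimal NumPy neural-network layers with explicit backward passes.

Tensors are NHWC float32.  Convolutions use im2col: windows are gathered
with ``sliding_window_view`` and the contraction is a single BLAS matmul,
which is what makes CPU training of the small U-Net practical.  Each layer
caches what its backward pass needs; ``params`` exposes [weight, grad]
pairs for the optimiser.
"""

from __future__ import annotations

import numpy as np


class Conv2D:
    """Same-padding 2-D convolution (He-initialised).

    Implemented as one GEMM per kernel tap on shifted views of the padded
    input, which keeps the working set small and the BLAS calls large.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = rng.normal(0.0, scale, size=(k, k, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None
        self._xshape = None

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        self._xshape = (n, h, w)
        out = np.empty((n * h * w, self.cout), dtype=np.result_type(x, self.W))
        out[:] = self.b
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, ki : ki + h, kj : kj + w, :].reshape(-1, self.cin)
                out += xs @ self.W[ki, kj]
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w = self._xshape
        k, p = self.k, self.k // 2
        xp = self._xp
        dflat = np.ascontiguousarray(dout.reshape(-1, self.cout), dtype=self.W.dtype)
        self.db += dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, ki : ki + h, kj : kj + w, :].reshape(-1, self.cin)
                self.dW[ki, kj] += xs.T @ dflat
                dxp[:, ki : ki + h, kj : kj + w, :] += (dflat @ self.W[ki, kj].T).reshape(n, h, w, self.cin)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def forward(self, x):
        n, h, w, c = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
        self._arg = win.argmax(axis=3)
        self._shape = x.shape
        return win.max(axis=3)

    def backward(self, dout):
        n, h, w, c = self._shape
        dwin = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
        idx = np.indices(self._arg.shape)
        dwin[idx[0], idx[1], idx[2], self._arg, idx[3]] = dout
        return dwin.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)


class UpNearest2:
    """2x nearest-neighbour upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class InstanceNorm:
    """Per-sample, per-channel standardisation over the spatial axes."""

    eps = 1e-5

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._y = (x - mu) * self._inv
        return self._y

    def backward(self, dout):
        y = self._y
        m1 = dout.mean(axis=(1, 2), keepdims=True)
        m2 = (dout * y).mean(axis=(1, 2), keepdims=True)
        return self._inv * (dout - m1 - y * m2)


class Dense:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / fin), size=(fin, fout)).astype(np.float32)
        self.b = np.zeros(fout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class Softplus:
    """log(1 + exp(x)), numerically stable; output is strictly positive."""

    def forward(self, x):
        self._sig = 1.0 / (1.0 + np.exp(-x))
        return np.logaddexp(0.0, x)

    def backward(self, dout):
        return dout * self._sig


class Adam:
    def __init__(self, param_pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = param_pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in param_pairs]
        self.v = [np.zeros_like(p) for p, _ in param_pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0
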