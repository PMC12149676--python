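"""Low-level layer primitives for the 3D U-Net.

The 3x3x3 convolutions dominate the cost of training, so their forward,
weight-gradient and input-gradient passes are JIT-compiled with numba (the
input gradient reuses the forward kernel with flipped, transposed weights).
Everything else (instance norm, ReLU, 2x pooling, transposed convolution,
1x1x1 projection) is cheap enough to stay in vectorized numpy.

Layers are small stateful classes with ``forward``/``backward`` and a
``params()`` iterator yielding ``(array, gradient)`` pairs; all activations
are float32.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "ConvBlock",
    "OutConv",
    "MaxPool",
    "UpConv",
    "Adam",
]


@njit(fastmath=True, cache=True)
def _conv3_fwd(xp, W, b, y):  # pragma: no cover - exercised via ConvBlock
    """y[co] = sum_ci conv3x3x3(xp[ci], W[co, ci]) + b[co]; xp is pre-padded.

    A row-length accumulator buffer keeps the inner loops register/L1
    resident, which roughly doubles throughput over accumulating into y.
    """
    Cout, D, H, Wd = y.shape
    Cin = xp.shape[0]
    acc = np.empty(Wd, dtype=xp.dtype)
    for co in range(Cout):
        for z in range(D):
            for yy in range(H):
                for x in range(Wd):
                    acc[x] = b[co]
                for ci in range(Cin):
                    for dz in range(3):
                        for dy in range(3):
                            w0 = W[co, ci, dz, dy, 0]
                            w1 = W[co, ci, dz, dy, 1]
                            w2 = W[co, ci, dz, dy, 2]
                            row = xp[ci, z + dz, yy + dy]
                            for x in range(Wd):
                                acc[x] += w0 * row[x] + w1 * row[x + 1] + w2 * row[x + 2]
                for x in range(Wd):
                    y[co, z, yy, x] = acc[x]


@njit(fastmath=True, cache=True)
def _conv3_dw(xp, dy, dW, db):  # pragma: no cover - exercised via ConvBlock
    """Accumulate dL/dW and dL/db from the padded input and output gradient."""
    Cout, D, H, Wd = dy.shape
    Cin = xp.shape[0]
    for co in range(Cout):
        s = 0.0
        for z in range(D):
            for yy in range(H):
                g = dy[co, z, yy]
                for x in range(Wd):
                    s += g[x]
                for ci in range(Cin):
                    for dz in range(3):
                        for dyy in range(3):
                            row = xp[ci, z + dz, yy + dyy]
                            a0 = 0.0
                            a1 = 0.0
                            a2 = 0.0
                            for x in range(Wd):
                                a0 += g[x] * row[x]
                                a1 += g[x] * row[x + 1]
                                a2 += g[x] * row[x + 2]
                            dW[co, ci, dz, dyy, 0] += a0
                            dW[co, ci, dz, dyy, 1] += a1
                            dW[co, ci, dz, dyy, 2] += a2
        db[co] += s


#: Smallest leading spatial dimension routed to the numba kernel; smaller
#: (deeper) levels run faster through BLAS shift-gemms.
_NUMBA_MIN_DIM = 24


def _conv3_fwd_gemm(xp, W, b, shape):
    Cin = xp.shape[0]
    D, H, Wd = shape
    Cout = W.shape[0]
    y = np.zeros((Cout, D * H * Wd), dtype=xp.dtype)
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                xs = np.ascontiguousarray(xp[:, dz:dz + D, dy:dy + H, dx:dx + Wd]).reshape(Cin, -1)
                y += W[:, :, dz, dy, dx] @ xs
    y += b[:, None]
    return y.reshape((Cout,) + shape)


def conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    if x.shape[1] >= _NUMBA_MIN_DIM:
        y = np.empty((W.shape[0],) + x.shape[1:], dtype=x.dtype)
        _conv3_fwd(xp, W, b, y)
        return y
    return _conv3_fwd_gemm(xp, W, b, x.shape[1:])


def conv3_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray, need_dx: bool = True
):
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    big = x.shape[1] >= _NUMBA_MIN_DIM
    if big:
        dW = np.zeros_like(W)
        db = np.zeros(W.shape[0], dtype=W.dtype)
        _conv3_dw(xp, dy, dW, db)
    else:
        Cin, Cout = x.shape[0], dy.shape[0]
        D, H, Wd = x.shape[1:]
        dyf = dy.reshape(Cout, -1)
        dW = np.empty_like(W)
        for dz in range(3):
            for dyy in range(3):
                for dx_ in range(3):
                    xs = np.ascontiguousarray(
                        xp[:, dz:dz + D, dyy:dyy + H, dx_:dx_ + Wd]
                    ).reshape(Cin, -1)
                    dW[:, :, dz, dyy, dx_] = dyf @ xs.T
        db = dyf.sum(axis=1).astype(W.dtype)
    dx = None
    if need_dx:
        # dx = conv(dy, W flipped in space and transposed in channels)
        Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (1, 1)))
        if big:
            dx = np.empty_like(x)
            _conv3_fwd(dyp, Wt, np.zeros(x.shape[0], dtype=x.dtype), dx)
        else:
            dx = _conv3_fwd_gemm(dyp, Wt, np.zeros(x.shape[0], dtype=x.dtype), x.shape[1:])
    return dx, dW, db


class ConvBlock:
    """conv(k3, s1, p1) -> instance norm -> ReLU, with cached backward."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 eps: float = 1e-5, dtype=np.float32):
        std = np.sqrt(2.0 / (c_in * 27))
        self.W = rng.normal(0.0, std, (c_out, c_in, 3, 3, 3)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gamma = np.ones(c_out, dtype=dtype)
        self.beta = np.zeros(c_out, dtype=dtype)
        self.eps = eps
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = conv3_forward(x, self.W, self.b)
        c = z.shape[0]
        flat = z.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(z.dtype)
        self._xhat = ((flat - mu) * self._inv).astype(z.dtype)
        a = self.gamma[:, None] * self._xhat + self.beta[:, None]
        y = np.maximum(a, 0.0).reshape(z.shape)
        self._relu_mask = y.reshape(c, -1) > 0
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        c = dy.shape[0]
        da = dy.reshape(c, -1) * self._relu_mask
        self.dbeta += da.sum(axis=1)
        self.dgamma += (da * self._xhat).sum(axis=1)
        dxhat = da * self.gamma[:, None]
        m = dxhat.shape[1]
        dz = self._inv * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=1, keepdims=True) / m
        )
        dz = dz.astype(dy.dtype).reshape(dy.shape)
        dx, dW, db = conv3_backward(self._x, self.W, dz, need_dx=need_dx)
        self.dW += dW
        self.db += db
        self._x = self._xhat = self._relu_mask = None
        return dx

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta


class OutConv:
    """1x1x1 convolution producing the S output logit channels."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, std, (c_out, c_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        c = x.shape[0]
        y = self.W @ x.reshape(c, -1) + self.b[:, None]
        return y.reshape((self.W.shape[0],) + x.shape[1:]).astype(x.dtype)

    def backward(self, dy: np.ndarray):
        s = dy.shape[0]
        dyf = dy.reshape(s, -1)
        xf = self._x.reshape(self._x.shape[0], -1)
        self.dW += dyf @ xf.T
        self.db += dyf.sum(axis=1)
        dx = (self.W.T @ dyf).astype(dy.dtype).reshape(self._x.shape)
        self._x = None
        return dx

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class MaxPool:
    """2x2x2 max pooling, stride 2; gradient routed to the (first) argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        v = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        v = v.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._argmax = v.argmax(axis=4)
        self._in_shape = x.shape
        return np.take_along_axis(v, self._argmax[..., None], axis=4)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = dy.shape
        scattered = np.zeros((c, d2, h2, w2, 8), dtype=dy.dtype)
        np.put_along_axis(scattered, self._argmax[..., None], dy[..., None], axis=4)
        v = scattered.reshape(c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        self._argmax = None
        return v.reshape(self._in_shape)

    def params(self):
        return iter(())


class UpConv:
    """Transposed convolution, kernel 2, stride 2 (2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / (c_in * 8))
        self.W = rng.normal(0.0, std, (c_in, c_out, 2, 2, 2)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        c_in, d, h, w = x.shape
        c_out = self.W.shape[1]
        xf = x.reshape(c_in, -1)
        y = np.empty((c_out, 2 * d, 2 * h, 2 * w), dtype=x.dtype)
        for a in range(2):
            for bb in range(2):
                for cc in range(2):
                    block = (self.W[:, :, a, bb, cc].T @ xf).astype(x.dtype)
                    y[:, a::2, bb::2, cc::2] = block.reshape(c_out, d, h, w)
        y += self.b[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_in = self._x.shape[0]
        xf = self._x.reshape(c_in, -1)
        dx = np.zeros_like(xf)
        for a in range(2):
            for bb in range(2):
                for cc in range(2):
                    g = dy[:, a::2, bb::2, cc::2].reshape(dy.shape[0], -1)
                    self.dW[:, :, a, bb, cc] += xf @ g.T
                    dx += self.W[:, :, a, bb, cc] @ g
        self.db += dy.sum(axis=(1, 2, 3))
        out = dx.astype(dy.dtype).reshape(self._x.shape)
        self._x = None
        return out

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class Adam:
    """Adam over the (param, grad) pairs of a list of layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [
            (np.zeros_like(p), np.zeros_like(p))
            for layer in layers
            for p, _ in layer.params()
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for _, g in layer.params():
                g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        i = 0
        for layer in self.layers:
            for p, g in layer.params():
                m, v = self.state[i]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                i += 1
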