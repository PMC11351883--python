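"""Minimal NumPy neural-network layers with explicit backpropagation.

This module implements exactly the layer set needed by the hemodynamic
regression network — 1-D convolution (im2col/GEMM), batch normalization,
ReLU/LeakyReLU, dropout, max-pooling, dense, and a (bidirectional) GRU —
each as a class with ``forward``/``backward`` methods and explicit
parameter/gradient lists, plus an Adam optimizer.  Data layout is
``(batch, length, channels)`` throughout; all backward passes are verified
against numerical gradients in the test suite.

The implementation favours large GEMMs (convolution and its input gradient
are both expressed as matrix products over unfolded windows) so that
single-CPU training of the full architecture stays tractable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "BatchNorm",
    "BiGRU",
    "Conv1D",
    "Dense",
    "Dropout",
    "GRUCell",
    "Layer",
    "LeakyReLU",
    "MaxPool1D",
    "ReLU",
    "mse_loss",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: holds aligned ``params`` and ``grads`` lists."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1D(Layer):
    """1-D convolution with 'same' padding via im2col + GEMM.

    Weights are stored as ``(kernel, in_channels, out_channels)``; the input
    gradient is computed as a transposed convolution (stride-dilated output
    gradient correlated with the flipped kernel), also as a GEMM.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel, stride
        self.dtype = dtype
        self.W = _glorot(rng, (kernel, in_channels, out_channels),
                         kernel * in_channels, kernel * out_channels, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pads(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)  # ceil
        pad_total = max((l_out - 1) * self.stride + self.k - length, 0)
        pl = pad_total // 2
        return l_out, pl, pad_total - pl

    def _tap(self, xp: np.ndarray, k: int, l_out: int) -> np.ndarray:
        return xp[:, k : k + (l_out - 1) * self.stride + 1 : self.stride]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # Per-tap batched GEMMs over strided views: one matmul per kernel
        # position avoids materializing the full im2col buffer.
        x = x.astype(self.dtype, copy=False)
        b, length, _ = x.shape
        l_out, pl, pr = self._pads(length)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        self._cache = (xp, length, pl, l_out)
        y = np.empty((b, l_out, self.cout), dtype=self.dtype)
        y[...] = self.b
        for k in range(self.k):
            y += self._tap(xp, k, l_out) @ self.W[k]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, length, pl, l_out = self._cache
        dy = dy.astype(self.dtype, copy=False)
        dxp = np.zeros_like(xp)
        for k in range(self.k):
            tap = self._tap(xp, k, l_out)
            self.grads[0][k] = np.matmul(tap.transpose(0, 2, 1), dy).sum(axis=0)
            dxp[:, k : k + (l_out - 1) * self.stride + 1 : self.stride] += dy @ self.W[k].T
        self.grads[1][...] = dy.sum(axis=(0, 1))
        return dxp[:, pl : pl + length]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (feature) axis."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        c = x.shape[-1]
        xr = x.reshape(-1, c)  # reductions over contiguous 2-D views
        if training:
            mean = xr.mean(axis=0)
            var = xr.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, training)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, training = self._cache
        c = dy.shape[-1]
        dyr = dy.reshape(-1, c)
        xhr = xhat.reshape(-1, c)
        dgamma = np.einsum("nc,nc->c", dyr, xhr)
        self.grads[0][...] = dgamma
        self.grads[1][...] = dyr.sum(axis=0)
        if not training:
            return dy * (self.gamma * inv)
        n = dyr.shape[0]
        # dL/dx = (gamma*inv/n) * (n*dy - sum(dy) - xhat*sum(dy*xhat))
        dx = dy - (self.grads[1] / n) - xhat * (dgamma / n)
        dx *= self.gamma * inv
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool1D(Layer):
    """Max pooling along time with stride equal to the pool size."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.pool == 1:
            self._cache = None
            return x
        b, length, c = x.shape
        lo = length // self.pool
        xr = x[:, : lo * self.pool].reshape(b, lo, self.pool, c)
        idx = xr.argmax(axis=2)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return dy
        idx, shape = self._cache
        b, lo, c = dy.shape
        dxr = np.zeros((b, lo, self.pool, c), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, : lo * self.pool] = dxr.reshape(b, lo * self.pool, c)
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class GRUCell(Layer):
    """Single-direction GRU unrolled over the full sequence.

    Gate order is (reset, update, candidate); the candidate pre-activation
    applies the reset gate to the *hidden* projection (as in cuDNN), which
    requires a separate hidden bias.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.h = hidden
        self.dtype = dtype
        self.Wx = _glorot(rng, (n_in, 3 * hidden), n_in, hidden, dtype)
        # Orthogonal init per gate for the recurrent weights.
        blocks = []
        for _ in range(3):
            q, _ = np.linalg.qr(rng.standard_normal((hidden, hidden)))
            blocks.append(q)
        self.Wh = np.concatenate(blocks, axis=1).astype(dtype)
        self.bx = np.zeros(3 * hidden, dtype=dtype)
        self.bh = np.zeros(3 * hidden, dtype=dtype)
        self.params = [self.Wx, self.Wh, self.bx, self.bh]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        h = self.h
        hidden = np.zeros((b, h), dtype=self.dtype)
        out = np.empty((b, t, h), dtype=self.dtype)
        gx_all = x @ self.Wx + self.bx  # one big GEMM for the input projections
        cache = []
        for step in range(t):
            gh = hidden @ self.Wh + self.bh
            gx = gx_all[:, step]
            r = _sigmoid(gx[:, :h] + gh[:, :h])
            z = _sigmoid(gx[:, h : 2 * h] + gh[:, h : 2 * h])
            n = np.tanh(gx[:, 2 * h :] + r * gh[:, 2 * h :])
            new_h = (1.0 - z) * n + z * hidden
            cache.append((hidden, r, z, n, gh[:, 2 * h :]))
            hidden = new_h
            out[:, step] = hidden
        self._cache = (x, cache)
        return out

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        b, t, _ = x.shape
        h = self.h
        dWx, dWh, dbx, dbh = (np.zeros_like(p) for p in self.params)
        dx = np.zeros_like(x)
        dh = np.zeros((b, h), dtype=self.dtype)
        dgx_all = np.zeros((b, t, 3 * h), dtype=self.dtype)
        for step in range(t - 1, -1, -1):
            h_prev, r, z, n, ghn = cache[step]
            dh = dh + d_out[:, step]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)
            dr = da_n * ghn
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            dgx = np.concatenate([da_r, da_z, da_n], axis=1)
            dgh = np.concatenate([da_r, da_z, da_n * r], axis=1)
            dgx_all[:, step] = dgx
            dWh += h_prev.T @ dgh
            dbh += dgh.sum(axis=0)
            dh = dh_prev + dgh @ self.Wh.T
        dx = dgx_all @ self.Wx.T
        dWx[...] = np.einsum("bti,btj->ij", x, dgx_all)
        dbx[...] = dgx_all.sum(axis=(0, 1))
        for g, val in zip(self.grads, (dWx, dWh, dbx, dbh)):
            g[...] = val
        return dx


class BiGRU(Layer):
    """Bidirectional GRU: forward and backward passes, outputs concatenated.

    ``forward`` returns the per-timestep concatenated outputs
    ``(batch, T, 2*hidden)`` in original time order; the backward cell's
    outputs are re-reversed so index 0 holds its final state.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.h = hidden
        self.fwd = GRUCell(n_in, hidden, rng, dtype)
        self.bwd = GRUCell(n_in, hidden, rng, dtype)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out_f = self.fwd.forward(x, training)
        out_b = self.bwd.forward(x[:, ::-1], training)[:, ::-1]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        h = self.h
        dx_f = self.fwd.backward(np.ascontiguousarray(d_out[:, :, :h]))
        dx_b = self.bwd.backward(np.ascontiguousarray(d_out[:, ::-1, h:]))[:, ::-1]
        return dx_f + dx_b


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer over the parameter/gradient lists of a set of layers."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    """Plain stochastic gradient descent (selectable alternative to Adam)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 0.001) -> None:
        self.params, self.grads, self.lr = params, grads, lr

    def step(self) -> None:
        for p, g in zip(self.params, self.grads):
            p -= self.lr * g
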