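"""Minimal feed-forward neural network kernels used by the sleep stagers.

Everything here is plain numpy with hand-written backward passes; the only
non-trivial numerics are the FFT-based temporal convolutions.  Layers follow
a tiny protocol: ``forward(x, train)`` caches what the matching
``backward(dy)`` needs, parameters live in ``params`` / ``grads`` lists of
arrays so an optimizer can iterate them generically.

Array layout for convolutional data is ``(batch, maps, rows, time)`` where
``rows`` is the preserved spatial axis (the 4 input derivations) and the
kernels slide along ``time`` only.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

DTYPE = np.float32


# ---------------------------------------------------------------------------
# FFT convolution along the last (time) axis
# ---------------------------------------------------------------------------

def conv1d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same' zero-padded convolution of ``x (B,C,R,T)`` with ``w (O,C,K)``.

    Returns ``(B,O,R,T)``.  Convolution (not correlation) semantics with the
    output aligned so that ``y[t]`` covers ``x[t-(K-1-p) .. t+p]``, where
    ``p = (K-1)//2``.
    """
    T, K = x.shape[-1], w.shape[-1]
    n = _fft.next_fast_len(T + K - 1, real=True)
    Xf = _fft.rfft(x, n)
    Wf = _fft.rfft(w.astype(x.dtype), n)
    Yf = np.einsum("bcrf,ocf->borf", Xf, Wf, optimize=True)
    y = _fft.irfft(Yf, n)[..., : T + K - 1]
    p = (K - 1) // 2
    return np.ascontiguousarray(y[..., p : p + T])


def conv1d_same_grads(x, w, dy):
    """Gradients of :func:`conv1d_same` w.r.t. ``x`` and ``w``."""
    T, K = x.shape[-1], w.shape[-1]
    p = (K - 1) // 2
    n = _fft.next_fast_len(T + K - 1, real=True)
    DYf = _fft.rfft(dy, n)
    # dx: convolve dy with time-reversed kernels, contract over output maps.
    RWf = _fft.rfft(w[..., ::-1].astype(x.dtype), n)
    dXf = np.einsum("borf,ocf->bcrf", DYf, RWf, optimize=True)
    dx_full = _fft.irfft(dXf, n)
    s0 = K - 1 - p
    dx = np.ascontiguousarray(dx_full[..., s0 : s0 + T])
    # dw: convolve dy with time-reversed input, contract over batch and rows.
    RXf = _fft.rfft(x[..., ::-1], n)
    dWf = np.einsum("borf,bcrf->ocf", DYf, RXf, optimize=True)
    dw_full = _fft.irfft(dWf, n)
    t0 = T - 1 - p
    dw = np.ascontiguousarray(dw_full[..., t0 : t0 + K])
    return dx, dw.astype(w.dtype)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class ConvTime(Layer):
    """1D convolution along time with kernels shared across the row axis."""

    def __init__(self, in_maps, out_maps, kernel, rng, dtype=DTYPE):
        super().__init__()
        fan_in = in_maps * kernel
        # He-normal initialization (ReLU follows every convolution here).
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_maps, in_maps, kernel))
        self.w = w.astype(dtype)
        self.b = np.zeros(out_maps, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return conv1d_same(x, self.w) + self.b[None, :, None, None]

    def backward(self, dy):
        dx, dw = conv1d_same_grads(self._x, self.w, dy)
        self.grads[0][...] = dw
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


class BatchNormMaps(Layer):
    """Batch normalization per feature map, statistics over (batch, rows, time).

    Training uses batch statistics; inference uses running averages updated
    with momentum 0.9.
    """

    def __init__(self, n_maps, momentum=0.9, eps=1e-5, dtype=DTYPE):
        super().__init__()
        self.gamma = np.ones(n_maps, dtype=dtype)
        self.beta = np.zeros(n_maps, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_maps, dtype=np.float64)
        self.running_var = np.ones(n_maps, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, n = self._cache
        axes = (0, 2, 3)
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dxhat_sum = dy.sum(axis=axes, keepdims=True)
        dxhat_dot = (dy * xhat).sum(axis=axes, keepdims=True)
        dx = g * (dy - dxhat_sum / n - xhat * dxhat_dot / n)
        self._cache = None
        return dx.astype(dy.dtype)


class AvgPoolTime(Layer):
    """Average pooling 1x2, stride 2, along the time axis."""

    def forward(self, x, train=False):
        B, C, R, T = x.shape
        self._T = T
        return x.reshape(B, C, R, T // 2, 2).mean(axis=-1)

    def backward(self, dy):
        return np.repeat(dy, 2, axis=-1) * 0.5


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=DTYPE, scale="he"):
        super().__init__()
        sd = np.sqrt((2.0 if scale == "he" else 1.0) / n_in)
        self.w = rng.normal(0.0, sd, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Dropout(Layer):
    def __init__(self, p=0.5):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class LSTM(Layer):
    """Unidirectional single-layer LSTM; returns the final hidden state.

    Input ``(B, L, n_in)``; gates ordered (input, forget, cell, output).
    Forget-gate bias initialized at 1.
    """

    def __init__(self, n_in, n_hidden, rng, dtype=DTYPE):
        super().__init__()
        self.n_hidden = n_hidden
        lim = np.sqrt(6.0 / (n_in + n_hidden))
        self.wx = rng.uniform(-lim, lim, size=(n_in, 4 * n_hidden)).astype(dtype)
        lim = np.sqrt(6.0 / (2 * n_hidden))
        self.wh = rng.uniform(-lim, lim, size=(n_hidden, 4 * n_hidden)).astype(dtype)
        self.b = np.zeros(4 * n_hidden, dtype=dtype)
        self.b[n_hidden : 2 * n_hidden] = 1.0
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x, train=False):
        B, L, _ = x.shape
        H = self.n_hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        cache = []
        for t in range(L):
            z = x[:, t] @ self.wx + h @ self.wh + self.b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, t], h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        self._cache = cache
        self._shape = x.shape
        return h

    def backward(self, dh_last):
        B, L, n_in = self._shape
        H = self.n_hidden
        for gr in self.grads:
            gr[...] = 0
        dx = np.zeros(self._shape, dtype=dh_last.dtype)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for t in range(L - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.grads[0] += xt.T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t] = dz @ self.wx.T
            dh = dz @ self.wh.T
            dc = dc * f
        self._cache = None
        return dx


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits.

    ``targets`` are integer class indices.
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), targets] + eps))
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(logits.dtype)
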