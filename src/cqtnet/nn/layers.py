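"""Differentiable layers on NumPy arrays.

Valid (un-padded) 1-D convolutions are evaluated in the frequency domain:
with an FFT length N >= L the circular cross-correlation equals the valid
linear one on the retained lags, and the three convolution products of the
backward pass (input grad, weight grad) are the matching spectral products.
This turns the dominant cost into stacked complex GEMMs, which is what
makes 10-fold cross-validation tractable on one CPU.

Conventions: activations are ``(batch, channels, length)`` for conv layers
and ``(batch, time, features)`` for the LSTM; every layer stores what its
backward pass needs, accumulates parameter gradients in ``.grads``, and
returns the input gradient.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft
from scipy.special import expit


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0


class Conv1d(Layer):
    """Valid cross-correlation, stride 1: (B, C_in, L) -> (B, C_out, L-K+1).

    Two equivalent evaluation paths: a direct im2col GEMM when the patch
    width ``C_in * K`` is small (cheap transforms dominate the FFT path
    there), and the spectral path otherwise. ``needs_input_grad=False``
    skips the input-gradient convolution — used at the first layer.
    """

    _DIRECT_PATCH_LIMIT = 512

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32,
                 needs_input_grad: bool = True) -> None:
        super().__init__()
        self.in_channels, self.out_channels, self.kernel_size = (
            in_channels, out_channels, kernel_size)
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.w = glorot_uniform((out_channels, in_channels, kernel_size),
                                fan_in, fan_out, rng, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cache = None

    @property
    def _direct(self) -> bool:
        return self.in_channels * self.kernel_size <= self._DIRECT_PATCH_LIMIT

    def _check(self, x):
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        if L < self.kernel_size:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel_size}")
        return B, C, L

    def forward(self, x, training=False, rng=None):
        B, C, L = self._check(x)
        K = self.kernel_size
        if self._direct:
            # (B, C, L_out, K) view -> (B*L_out, C*K) @ (C*K, O)
            win = np.lib.stride_tricks.sliding_window_view(x, K, axis=-1)
            cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
                B * (L - K + 1), C * K)
            y = cols @ self.w.reshape(self.out_channels, C * K).T + self.b
            self._cache = (cols, L, x.dtype)
            return np.ascontiguousarray(
                y.reshape(B, L - K + 1, self.out_channels).transpose(0, 2, 1))
        N = sfft.next_fast_len(L)
        xh = sfft.rfft(x, N)                       # (B, C, F)
        wh = sfft.rfft(self.w, N)                  # (O, C, F)
        yh = (xh.transpose(2, 0, 1) @ np.conj(wh).transpose(2, 1, 0))  # (F, B, O)
        y = sfft.irfft(yh.transpose(1, 2, 0), N)[..., : L - K + 1]
        y = y + self.b[:, None]
        self._cache = (xh, wh, L, N, x.dtype)
        return y.astype(x.dtype, copy=False)

    def backward(self, dy):
        K = self.kernel_size
        if self._direct:
            cols, L, dtype = self._cache
            B, O, L_out = dy.shape
            dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(
                B * L_out, O)
            dw = (dy_flat.T @ cols).reshape(self.w.shape)
            self.grads[0] += dw.astype(self.w.dtype, copy=False)
            self.grads[1] += dy.sum(axis=(0, 2)).astype(self.b.dtype, copy=False)
            if not self.needs_input_grad:
                return None
            dcols = (dy_flat @ self.w.reshape(O, -1)).reshape(
                B, L_out, self.in_channels, K)
            dx = np.zeros((B, self.in_channels, L), dtype=dtype)
            for k in range(K):
                dx[:, :, k : k + L_out] += dcols[:, :, :, k].transpose(0, 2, 1)
            return dx
        xh, wh, L, N, dtype = self._cache
        dyh = sfft.rfft(dy, N)                     # (B, O, F)
        # weight gradient: correlation of x with dy over the batch
        dwh = (np.conj(dyh).transpose(2, 1, 0) @ xh.transpose(2, 0, 1))  # (F, O, C)
        dw = sfft.irfft(dwh.transpose(1, 2, 0), N)[..., :K]
        self.grads[0] += dw.astype(self.w.dtype, copy=False)
        self.grads[1] += dy.sum(axis=(0, 2)).astype(self.b.dtype, copy=False)
        if not self.needs_input_grad:
            return None
        # input gradient: full convolution of dy with w
        dxh = dyh.transpose(2, 0, 1) @ wh.transpose(2, 0, 1)           # (F, B, C)
        dx = sfft.irfft(dxh.transpose(1, 2, 0), N)[..., :L]
        return dx.astype(dtype, copy=False)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        y = np.maximum(x, 0)
        self._mask = y > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """Max pooling, size 2, stride 2; an odd trailing sample is dropped.

    Ties go to the earlier sample, matching argmax-first semantics.
    """

    def forward(self, x, training=False, rng=None):
        L2 = x.shape[-1] // 2
        a = x[..., : 2 * L2 : 2]
        b = x[..., 1 : 2 * L2 : 2]
        self._right = b > a
        self._in_shape = x.shape
        return np.where(self._right, b, a)

    def backward(self, dy):
        L2 = dy.shape[-1]
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[..., : 2 * L2 : 2] = dy * ~self._right
        dx[..., 1 : 2 * L2 : 2] = dy * self._right
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.rate).astype(x.dtype) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    return expit(x)


class LSTM(Layer):
    """Single LSTM layer, tanh activations, returning all time steps.

    Input ``(B, T, F)`` -> output ``(B, T, H)``. Gate order i, f, g, o;
    forget-gate bias initialized to 1.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.in_features, self.hidden = in_features, hidden
        self.wx = glorot_uniform((in_features, 4 * hidden), in_features, hidden,
                                 rng, dtype)
        # orthogonal recurrent blocks, one per gate
        blocks = []
        for _ in range(4):
            a = rng.normal(size=(hidden, hidden))
            q, r = np.linalg.qr(a)
            blocks.append(q * np.sign(np.diag(r)))
        self.wh = np.concatenate(blocks, axis=1).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden : 2 * hidden] = 1.0
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False, rng=None):
        B, T, F = x.shape
        H = self.hidden
        xp = x.reshape(B * T, F) @ self.wx + self.b
        xp = xp.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        gates = np.empty((B, T, 4 * H), dtype=x.dtype)
        cs = np.empty((B, T, H), dtype=x.dtype)
        tcs = np.empty((B, T, H), dtype=x.dtype)
        hs = np.empty((B, T, H), dtype=x.dtype)
        for t in range(T):
            z = xp[:, t] + h @ self.wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
            cs[:, t], tcs[:, t], hs[:, t] = c, tc, h
        self._cache = (x, gates, cs, tcs, hs)
        return hs

    def backward(self, dy):
        x, gates, cs, tcs, hs = self._cache
        B, T, F = x.shape
        H = self.hidden
        dxp = np.empty((B, T, 4 * H), dtype=dy.dtype)
        dwh = np.zeros_like(self.wh, dtype=np.float64)
        dh_next = np.zeros((B, H), dtype=dy.dtype)
        dc_next = np.zeros((B, H), dtype=dy.dtype)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dy.dtype)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dy.dtype)
            dh = dy[:, t] + dh_next
            do = dh * tcs[:, t]
            dc = dh * o * (1 - tcs[:, t] ** 2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dxp[:, t] = dz
            dwh += h_prev.T @ dz
            dh_next = dz @ self.wh.T
        self.grads[0] += (x.reshape(B * T, F).T @ dxp.reshape(B * T, 4 * H)).astype(
            self.wx.dtype)
        self.grads[1] += dwh.astype(self.wh.dtype)
        self.grads[2] += dxp.sum(axis=(0, 1)).astype(self.b.dtype)
        return (dxp.reshape(B * T, 4 * H) @ self.wx.T).reshape(B, T, F).astype(
            dy.dtype, copy=False)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.w = glorot_uniform((in_features, out_features), in_features,
                                out_features, rng, dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0] += (self._x.T @ dy).astype(self.w.dtype, copy=False)
        self.grads[1] += dy.sum(axis=0).astype(self.b.dtype, copy=False)
        return dy @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over the batch and its logit gradient."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam optimizer over a flat list of parameter/gradient pairs."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.0015,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g64 = g.astype(np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g64
            v *= self.beta2
            v += (1 - self.beta2) * g64**2
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
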