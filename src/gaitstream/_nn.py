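"""Minimal numpy neural-network backend.

Implements exactly what the two streams need: 3x3 same-padding
convolutions (as 9 GEMMs, channels-last), 2x2 max pooling, dense
layers, a single-layer LSTM with BPTT, softmax cross-entropy and Adam.
Everything is float32 and deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

F32 = np.float32


def stable_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with max-subtraction; rows sum to 1."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("softmax requires finite logits")
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = probs[np.arange(len(y)), y]
    return float(-np.mean(np.log(np.maximum(p, 1e-12))))


class Adam:
    """Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray], clip_norm: Optional[float] = None) -> None:
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# convolutional pieces (channels-last: activations are (B, H, W, C))
# ---------------------------------------------------------------------------

def he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Same-padding stride-1 3x3 conv.  w is (3, 3, Cin, Cout).

    Returns (y, xp) where xp is the padded input kept for backward.
    """
    B, H, W, Cin = x.shape
    Cout = w.shape[-1]
    xp = np.zeros((B, H + 2, W + 2, Cin), dtype=F32)
    xp[:, 1:-1, 1:-1, :] = x
    y = np.empty((B * H * W, Cout), dtype=F32)
    y[:] = b
    for i in range(3):
        for j in range(3):
            patch = xp[:, i:i + H, j:j + W, :].reshape(B * H * W, Cin)
            y += patch @ w[i, j]
    return y.reshape(B, H, W, Cout), xp


def conv3x3_backward(dy: np.ndarray, xp: np.ndarray, w: np.ndarray):
    """Gradients for conv3x3_forward. Returns (dx, dw, db)."""
    B, H, W, Cout = dy.shape
    Cin = w.shape[2]
    dyf = dy.reshape(B * H * W, Cout)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            patch = xp[:, i:i + H, j:j + W, :].reshape(B * H * W, Cin)
            dw[i, j] = patch.T @ dyf
            dxp[:, i:i + H, j:j + W, :] += (dyf @ w[i, j].T).reshape(B, H, W, Cin)
    db = dyf.sum(axis=0)
    return dxp[:, 1:-1, 1:-1, :], dw, db


def maxpool2_forward(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """2x2 stride-2 max pool; even H, W assumed."""
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
    y = xr.max(axis=(2, 4))
    mask = xr == y[:, :, None, :, None, :]
    return y, mask


def maxpool2_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    B, Hh, _, Wh, _, C = mask.shape
    dxr = mask * dy[:, :, None, :, None, :]
    return dxr.reshape(B, Hh * 2, Wh * 2, C)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0, out=x)


# ---------------------------------------------------------------------------
# LSTM (single direction, batch-first, uniform sequence length with masking)
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Fused-gate LSTM weights; gate order (i, f, g, o)."""

    wx: np.ndarray  # (D, 4H)
    wh: np.ndarray  # (H, 4H)
    b: np.ndarray   # (4H,)

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int, hidden: int) -> "LSTMParams":
        s = 1.0 / np.sqrt(hidden)
        wx = (rng.uniform(-s, s, (d_in, 4 * hidden))).astype(F32)
        wh = (rng.uniform(-s, s, (hidden, 4 * hidden))).astype(F32)
        b = np.zeros(4 * hidden, dtype=F32)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        return cls(wx, wh, b)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_forward(x: np.ndarray, p: LSTMParams, lengths: np.ndarray):
    """Run the LSTM over (B, T, D); return per-sample hidden state at the
    last valid timestep plus caches for backward."""
    B, T, D = x.shape
    H = p.wh.shape[0]
    h = np.zeros((B, H), dtype=F32)
    c = np.zeros((B, H), dtype=F32)
    caches = []
    h_last = np.zeros((B, H), dtype=F32)
    for t in range(T):
        gates = x[:, t, :] @ p.wx + h @ p.wh + p.b
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H:2 * H])
        g = np.tanh(gates[:, 2 * H:3 * H])
        o = _sigmoid(gates[:, 3 * H:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((x[:, t, :], h, c, i, f, g, o, c_new, tanh_c))
        h, c = h_new, c_new
        at_end = lengths == t + 1
        if np.any(at_end):
            h_last[at_end] = h[at_end]
    return h_last, caches


def lstm_backward(dh_last: np.ndarray, caches, p: LSTMParams, lengths: np.ndarray):
    """BPTT. dh_last is dL/d(h at each sample's last valid step)."""
    B, H = dh_last.shape
    T = len(caches)
    dwx = np.zeros_like(p.wx)
    dwh = np.zeros_like(p.wh)
    db = np.zeros_like(p.b)
    dx = np.zeros((B, T, p.wx.shape[0]), dtype=F32)
    dh = np.zeros((B, H), dtype=F32)
    dc = np.zeros((B, H), dtype=F32)
    for t in range(T - 1, -1, -1):
        xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c = caches[t]
        at_end = lengths == t + 1
        if np.any(at_end):
            dh = dh.copy()
            dh[at_end] += dh_last[at_end]
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dgates = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        # padded steps (t >= length) contribute nothing
        pad = lengths <= t
        if np.any(pad):
            dgates[pad] = 0.0
        dwx += xt.T @ dgates
        dwh += h_prev.T @ dgates
        db += dgates.sum(axis=0)
        dx[:, t, :] = dgates @ p.wx.T
        dh = dgates @ p.wh.T
        dc = dc * f
        if np.any(pad):
            dh[pad] = 0.0
            dc[pad] = 0.0
    return dx, dwx, dwh, db


class ReduceLROnPlateau:
    """Divide lr by ``factor`` when the monitored loss stops improving."""

    def __init__(self, opt: Adam, factor: float = 10.0, patience: int = 10,
                 min_lr: float = 1e-5, rel_threshold: float = 1e-3):
        self.opt = opt
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.rel_threshold = rel_threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best * (1.0 - self.rel_threshold):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr = max(self.opt.lr / self.factor, self.min_lr)
                self.bad_epochs = 0
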