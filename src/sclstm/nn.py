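"""Minimal NumPy neural-network primitives for the twin-LSTM pair scorer.

Implements exactly what the model needs: a batched LSTM forward/backward
(backpropagation through time with a gradient injected at the final hidden
state only), dense layers, logistic sigmoid, binary cross-entropy, and Adam.
Everything is float64 for reproducibility of the bit-stable-seed contract.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_lstm_params(input_dim: int, hidden: int, rng: np.random.Generator) -> dict:
    """Glorot-uniform gate weights; forget-gate bias starts at 1."""
    def glorot(fan_in, fan_out, size):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=size)

    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0
    return {
        "Wx": glorot(input_dim, hidden, (input_dim, 4 * hidden)),
        "Wh": glorot(hidden, hidden, (hidden, 4 * hidden)),
        "b": b,
    }


def init_dense_params(fan_in: int, fan_out: int, rng: np.random.Generator) -> dict:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return {
        "W": rng.uniform(-limit, limit, size=(fan_in, fan_out)),
        "b": np.zeros(fan_out),
    }


def lstm_forward(X: np.ndarray, params: dict) -> tuple[np.ndarray, list]:
    """Run an LSTM over X of shape (batch, time, input_dim).

    Returns the final hidden state (batch, hidden) and the per-step cache
    needed for backpropagation. Gate order in the packed weight matrices is
    input, forget, candidate, output.
    """
    B, T, _ = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    for t in range(T):
        x_t = X[:, t, :]
        z = x_t @ Wx + h @ Wh + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        cache.append((x_t, h, c, i, f, g, o, tc))
        h = o * tc
        c = c_new
    return h, cache


def lstm_backward(dh_final: np.ndarray, cache: list, params: dict) -> dict:
    """BPTT given the loss gradient at the final hidden state only."""
    Wx, Wh = params["Wx"], params["Wh"]
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for x_t, h_prev, c_prev, i, f, g, o, tc in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
        dc = dc * f
    return {"Wx": dWx, "Wh": dWh, "b": db}


class Adam:
    """Standard Adam over a flat dict-of-dicts parameter tree."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: {kk: np.zeros_like(v) for kk, v in grp.items()}
                  for k, grp in params.items()}
        self.v = {k: {kk: np.zeros_like(v) for kk, v in grp.items()}
                  for k, grp in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for k, grp in grads.items():
            for kk, g in grp.items():
                m = self.m[k][kk] = self.beta1 * self.m[k][kk] + (1 - self.beta1) * g
                v = self.v[k][kk] = self.beta2 * self.v[k][kk] + (1 - self.beta2) * g * g
                params[k][kk] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
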