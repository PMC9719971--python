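"""Minimal batched LSTM primitives in NumPy.

Forward passes cache everything needed for exact backpropagation through
time; padded steps (beyond each sequence's length) carry the hidden and cell
state through unchanged, so gradients are exact for variable-length batches.
All parameters live in plain dicts of float64 arrays, which keeps training
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_lstm",
    "lstm_forward",
    "lstm_backward",
    "reverse_padded",
    "Adam",
    "glorot",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape if shape is not None else (fan_in, fan_out))


def init_lstm(rng: np.random.Generator, d_in: int, d_hidden: int) -> dict:
    """Gate order: input, forget, cell candidate, output. Forget bias +1."""
    b = np.zeros(4 * d_hidden)
    b[d_hidden : 2 * d_hidden] = 1.0
    return {
        "W": glorot(rng, d_in, 4 * d_hidden, (d_in, 4 * d_hidden)),
        "U": glorot(rng, d_hidden, 4 * d_hidden, (d_hidden, 4 * d_hidden)),
        "b": b,
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_forward(p: dict, X: np.ndarray, lengths: np.ndarray):
    """Run an LSTM over ``X`` (B, T, D) with per-row valid ``lengths``.

    Returns the hidden sequence H (B, T, Hd) and a cache for the backward
    pass.  States freeze once a row's valid prefix ends.
    """
    B, T, _ = X.shape
    Hd = p["U"].shape[0]
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    H = np.zeros((B, T, Hd))
    C = np.zeros((B, T, Hd))
    gates = np.zeros((B, T, 4 * Hd))
    c_tilde = np.zeros((B, T, Hd))
    h = np.zeros((B, Hd))
    c = np.zeros((B, Hd))
    for t in range(T):
        a = X[:, t] @ p["W"] + h @ p["U"] + p["b"]
        i = _sigmoid(a[:, :Hd])
        f = _sigmoid(a[:, Hd : 2 * Hd])
        g = np.tanh(a[:, 2 * Hd : 3 * Hd])
        o = _sigmoid(a[:, 3 * Hd :])
        ct = f * c + i * g
        ht = o * np.tanh(ct)
        m = mask[:, t : t + 1]
        gates[:, t] = np.concatenate([i, f, g, o], axis=1)
        c_tilde[:, t] = ct
        c = m * ct + (1.0 - m) * c
        h = m * ht + (1.0 - m) * h
        H[:, t] = h
        C[:, t] = c
    cache = {"X": X, "mask": mask, "H": H, "C": C, "gates": gates, "c_tilde": c_tilde}
    return H, cache


def lstm_backward(p: dict, cache: dict, dH: np.ndarray):
    """Exact BPTT.  ``dH`` holds upstream gradients on every output position
    (zeros where unused).  Returns (dX, grads)."""
    X, mask = cache["X"], cache["mask"]
    H, C, gates, c_tilde = cache["H"], cache["C"], cache["gates"], cache["c_tilde"]
    B, T, Hd = H.shape
    dW = np.zeros_like(p["W"])
    dU = np.zeros_like(p["U"])
    db = np.zeros_like(p["b"])
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, Hd))
    dc_next = np.zeros((B, Hd))
    for t in range(T - 1, -1, -1):
        m = mask[:, t : t + 1]
        i = gates[:, t, :Hd]
        f = gates[:, t, Hd : 2 * Hd]
        g = gates[:, t, 2 * Hd : 3 * Hd]
        o = gates[:, t, 3 * Hd :]
        ct = c_tilde[:, t]
        tanh_ct = np.tanh(ct)
        h_prev = H[:, t - 1] if t > 0 else np.zeros((B, Hd))
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, Hd))

        dh = dH[:, t] + dh_next
        dc_t = dc_next
        dh_tilde = m * dh
        dh_carry = (1.0 - m) * dh
        do = dh_tilde * tanh_ct
        dct = dh_tilde * o * (1.0 - tanh_ct**2) + m * dc_t
        dc_carry = (1.0 - m) * dc_t
        df = dct * c_prev
        di = dct * g
        dg = dct * i
        dc_prev = dct * f + dc_carry

        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        dW += X[:, t].T @ da
        dU += h_prev.T @ da
        db += da.sum(axis=0)
        dX[:, t] = da @ p["W"].T
        dh_next = da @ p["U"].T + dh_carry
        dc_next = dc_prev
    return dX, {"W": dW, "U": dU, "b": db}


def reverse_padded(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's valid prefix in place along time; padding stays put.
    Applying it twice with the same lengths is the identity."""
    B, T = X.shape[:2]
    ar = np.arange(T)[None, :]
    idx = np.where(ar < lengths[:, None], lengths[:, None] - 1 - ar, ar)
    if X.ndim == 3:
        return np.take_along_axis(X, idx[:, :, None], axis=1)
    return np.take_along_axis(X, idx, axis=1)


class Adam:
    """Plain Adam over a nested dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = _tree_map(np.zeros_like, params)
        self.v = _tree_map(np.zeros_like, params)

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        self._step(params, grads, self.m, self.v)

    def _step(self, p, g, m, v):
        for key in p:
            if isinstance(p[key], dict):
                self._step(p[key], g[key], m[key], v[key])
            else:
                m[key][...] = self.b1 * m[key] + (1 - self.b1) * g[key]
                v[key][...] = self.b2 * v[key] + (1 - self.b2) * g[key] ** 2
                mhat = m[key] / (1 - self.b1**self.t)
                vhat = v[key] / (1 - self.b2**self.t)
                p[key][...] = p[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _tree_map(fn, tree):
    return {k: _tree_map(fn, val) if isinstance(val, dict) else fn(val) for k, val in tree.items()}


def tree_zeros_like(tree):
    return _tree_map(np.zeros_like, tree)


def tree_add_(acc, other):
    for k in acc:
        if isinstance(acc[k], dict):
            tree_add_(acc[k], other[k])
        else:
            acc[k] += other[k]
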