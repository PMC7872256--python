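"""Bidirectional LSTM encoder layers with hand-written backpropagation.

Parameters per direction: ``Wx`` (D_in, 4H), ``Wh`` (H, 4H), ``b`` (4H,)
with gate layout (input, forget, output, cell) — the three sigmoid gates
contiguous so one ``expit`` call covers them — and forget-gate bias
initialized to 1.  All compute is float32.  Batches are padded at the tail;
padded positions are masked out of both states and gradients.  The backward
direction is run by reversing each sequence within its own length, so
padding stays at the tail in both directions and the same cell code serves
both.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def init_cell_params(
    rng: np.random.Generator, d_in: int, hidden: int
) -> dict[str, np.ndarray]:
    b = np.zeros(4 * hidden, dtype=DTYPE)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias
    return {
        "Wx": glorot(rng, (d_in, 4 * hidden)),
        "Wh": glorot(rng, (hidden, 4 * hidden)),
        "b": b,
    }


def lstm_forward(
    params: dict[str, np.ndarray], x: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Run one LSTM direction over (B, T, D) inputs; returns (B, T, H)
    hidden states (zero at padding) and a cache for the backward pass."""
    B, T, D = x.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H), dtype=DTYPE)
    c = np.zeros((B, H), dtype=DTYPE)
    hs = np.empty((B, T, H), dtype=DTYPE)
    gates = np.empty((B, T, 4 * H), dtype=DTYPE)
    tanh_cs = np.empty((B, T, H), dtype=DTYPE)
    h_prevs = np.empty((B, T, H), dtype=DTYPE)
    c_prevs = np.empty((B, T, H), dtype=DTYPE)
    xW = x.reshape(B * T, D) @ params["Wx"]
    xW = xW.reshape(B, T, 4 * H) + params["b"]
    for t in range(T):
        m = mask[:, t][:, None]
        a = xW[:, t, :] + h @ params["Wh"]
        a[:, : 3 * H] = expit(a[:, : 3 * H])
        np.tanh(a[:, 3 * H :], out=a[:, 3 * H :])
        i = a[:, :H]
        f = a[:, H : 2 * H]
        o = a[:, 2 * H : 3 * H]
        g = a[:, 3 * H :]
        h_prevs[:, t] = h
        c_prevs[:, t] = c
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h = o * tc * m
        c = c_new * m
        hs[:, t] = h
        gates[:, t] = a
        tanh_cs[:, t] = tc
    return hs, {
        "x": x,
        "mask": mask,
        "gates": gates,
        "tanh_c": tanh_cs,
        "h_prev": h_prevs,
        "c_prev": c_prevs,
    }


def lstm_backward(
    params: dict[str, np.ndarray], cache: dict, d_hs: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop through time; returns (d_x, grads) for one direction."""
    x, mask = cache["x"], cache["mask"]
    B, T, D = x.shape
    H = params["Wh"].shape[0]
    WxT = np.ascontiguousarray(params["Wx"].T)
    WhT = np.ascontiguousarray(params["Wh"].T)
    das = np.empty((B, T, 4 * H), dtype=DTYPE)
    dh_next = np.zeros((B, H), dtype=DTYPE)
    dc_next = np.zeros((B, H), dtype=DTYPE)
    da = np.empty((B, 4 * H), dtype=DTYPE)
    for t in range(T - 1, -1, -1):
        m = mask[:, t][:, None]
        a = cache["gates"][:, t]
        i = a[:, :H]
        f = a[:, H : 2 * H]
        o = a[:, 2 * H : 3 * H]
        g = a[:, 3 * H :]
        tc = cache["tanh_c"][:, t]
        dh = (d_hs[:, t, :] + dh_next) * m
        dc = (dc_next + dh * o * (1.0 - tc * tc)) * m
        da[:, :H] = dc * g * i * (1.0 - i)
        da[:, H : 2 * H] = dc * cache["c_prev"][:, t] * f * (1.0 - f)
        da[:, 2 * H : 3 * H] = dh * tc * o * (1.0 - o)
        da[:, 3 * H :] = dc * i * (1.0 - g * g)
        das[:, t] = da
        dh_next = da @ WhT
        dc_next = dc * f
    das_flat = das.reshape(B * T, 4 * H)
    grads = {
        "Wx": x.reshape(B * T, D).T @ das_flat,
        "Wh": cache["h_prev"].reshape(B * T, H).T @ das_flat,
        "b": das_flat.sum(axis=0),
    }
    dx = (das_flat @ WxT).reshape(B, T, D)
    return dx, grads


def reverse_indices(lengths: np.ndarray, T: int) -> np.ndarray:
    """(B, T) gather indices that reverse each sequence within its length,
    leaving padding positions in place."""
    t = np.arange(T)[None, :]
    rev = lengths[:, None] - 1 - t
    return np.where(t < lengths[:, None], rev, t)


def gather_time(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.take_along_axis(x, idx[:, :, None], axis=1)


class BiLSTMLayer:
    """One bidirectional layer: forward and reversed cells, outputs
    concatenated to (B, T, 2H)."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        self.fwd = init_cell_params(rng, d_in, hidden)
        self.bwd = init_cell_params(rng, d_in, hidden)

    def parameters(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for d, p in (("f", self.fwd), ("b", self.bwd)):
            for k, v in p.items():
                out[f"{prefix}.{d}.{k}"] = v
        return out

    def load(self, prefix: str, params: dict[str, np.ndarray]) -> None:
        for d, p in (("f", self.fwd), ("b", self.bwd)):
            for k in p:
                p[k] = params[f"{prefix}.{d}.{k}"]

    def forward(
        self, x: np.ndarray, mask: np.ndarray, lengths: np.ndarray
    ) -> tuple[np.ndarray, dict]:
        T = x.shape[1]
        ridx = reverse_indices(lengths, T)
        h_f, cache_f = lstm_forward(self.fwd, x, mask)
        x_rev = gather_time(x, ridx)
        h_b_rev, cache_b = lstm_forward(self.bwd, x_rev, mask)
        h_b = gather_time(h_b_rev, ridx)
        out = np.concatenate([h_f, h_b], axis=2)
        return out, {"cache_f": cache_f, "cache_b": cache_b, "ridx": ridx}

    def backward(
        self, cache: dict, d_out: np.ndarray
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        H = self.hidden
        ridx = cache["ridx"]
        d_hf = np.ascontiguousarray(d_out[:, :, :H])
        d_hb = gather_time(np.ascontiguousarray(d_out[:, :, H:]), ridx)
        dx_f, g_f = lstm_backward(self.fwd, cache["cache_f"], d_hf)
        dx_b_rev, g_b = lstm_backward(self.bwd, cache["cache_b"], d_hb)
        dx = dx_f + gather_time(dx_b_rev, ridx)
        grads = {f"f.{k}": v for k, v in g_f.items()}
        grads.update({f"b.{k}": v for k, v in g_b.items()})
        return dx, grads
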