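"""Fused numba kernels for the LSTM cell pointwise update.

The gate nonlinearities (3 sigmoids + 2 tanh per cell step) dominate CPU
time when expressed as separate graph ops; fusing them into one op with a
hand-derived backward keeps the autodiff graph small. These ops support
first-order gradients only — nothing in the package differentiates through
an LSTM twice (the gradient penalty touches only the MLP critic).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tensor import Tensor


@njit(cache=True, fastmath=True)
def _lstm_fwd_kernel(gates, c_prev):
    B, G = gates.shape
    H = G // 4
    h = np.empty((B, H), dtype=gates.dtype)
    c = np.empty((B, H), dtype=gates.dtype)
    acts = np.empty((B, 5 * H), dtype=gates.dtype)  # i,f,g,o,tanh(c)
    for b in range(B):
        for j in range(H):
            i = 1.0 / (1.0 + np.exp(-gates[b, j]))
            f = 1.0 / (1.0 + np.exp(-gates[b, H + j]))
            g = np.tanh(gates[b, 2 * H + j])
            o = 1.0 / (1.0 + np.exp(-gates[b, 3 * H + j]))
            cc = f * c_prev[b, j] + i * g
            tc = np.tanh(cc)
            c[b, j] = cc
            h[b, j] = o * tc
            acts[b, j] = i
            acts[b, H + j] = f
            acts[b, 2 * H + j] = g
            acts[b, 3 * H + j] = o
            acts[b, 4 * H + j] = tc
    return h, c, acts


@njit(cache=True, fastmath=True)
def _lstm_bwd_kernel(dh, dc_out, acts, c_prev):
    B, H = dh.shape
    dgates = np.empty((B, 4 * H), dtype=dh.dtype)
    dc_prev = np.empty((B, H), dtype=dh.dtype)
    for b in range(B):
        for j in range(H):
            i = acts[b, j]
            f = acts[b, H + j]
            g = acts[b, 2 * H + j]
            o = acts[b, 3 * H + j]
            tc = acts[b, 4 * H + j]
            dc = dc_out[b, j] + dh[b, j] * o * (1.0 - tc * tc)
            dgates[b, j] = dc * g * i * (1.0 - i)
            dgates[b, H + j] = dc * c_prev[b, j] * f * (1.0 - f)
            dgates[b, 2 * H + j] = dc * i * (1.0 - g * g)
            dgates[b, 3 * H + j] = dh[b, j] * tc * o * (1.0 - o)
            dc_prev[b, j] = dc * f
    return dgates, dc_prev


def lstm_pointwise(gates: Tensor, c_prev: Tensor) -> tuple[Tensor, Tensor]:
    """Fused i,f,g,o gate update: returns (h, c). First-order grads only."""
    H = gates.shape[1] // 4
    h_data, c_data, acts = _lstm_fwd_kernel(gates.data, c_prev.data)
    hc = np.concatenate([h_data, c_data], axis=1)

    def backward(grad: Tensor):
        gd = grad.data
        dgates, dc_prev = _lstm_bwd_kernel(
            np.ascontiguousarray(gd[:, :H]), np.ascontiguousarray(gd[:, H:]),
            acts, c_prev.data)
        return Tensor(dgates), Tensor(dc_prev)

    out = Tensor._make(hc, (gates, c_prev), backward)
    return out[:, :H], out[:, H:]
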