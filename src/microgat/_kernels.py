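"""Numba-fused edge kernels for the GATv2 message-passing hot path.

These avoid materializing (n_edges, n_heads * head_dim) intermediates for
the attention-logit and aggregation steps; on one CPU core they roughly
halve the cost of a training step relative to the pure-NumPy composition
of gather / LeakyReLU / multiply / segment-sum.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def edge_scores_fwd(xq, xk, att, src, dst, slope):
    """scores[e, k] = sum_f att[k, f] * LeakyReLU(xq[dst_e, kF+f] + xk[src_e, kF+f])."""
    E = src.shape[0]
    K, F = att.shape
    scores = np.zeros((E, K), dtype=xq.dtype)
    for e in range(E):
        i = dst[e]
        j = src[e]
        for k in range(K):
            acc = 0.0
            base = k * F
            for f in range(F):
                c = base + f
                t = xq[i, c] + xk[j, c]
                if t < 0.0:
                    t *= slope
                acc += t * att[k, f]
            scores[e, k] = acc
    return scores


@njit(cache=True, fastmath=True)
def edge_scores_bwd(g, xq, xk, att, src, dst, slope):
    E = src.shape[0]
    K, F = att.shape
    dxq = np.zeros_like(xq)
    dxk = np.zeros_like(xk)
    datt = np.zeros_like(att)
    for e in range(E):
        i = dst[e]
        j = src[e]
        for k in range(K):
            ge = g[e, k]
            if ge == 0.0:
                continue
            base = k * F
            for f in range(F):
                c = base + f
                t = xq[i, c] + xk[j, c]
                if t < 0.0:
                    l = t * slope
                    factor = slope
                else:
                    l = t
                    factor = 1.0
                gl = ge * att[k, f] * factor
                dxq[i, c] += gl
                dxk[j, c] += gl
                datt[k, f] += ge * l
    return dxq, dxk, datt


@njit(cache=True, fastmath=True)
def aggregate_fwd(alpha, xk, src, dst, n_nodes):
    """out[i, kF+f] = sum_{e: dst_e = i} alpha[e, k] * xk[src_e, kF+f]."""
    E = src.shape[0]
    K = alpha.shape[1]
    C = xk.shape[1]
    F = C // K
    out = np.zeros((n_nodes, C), dtype=xk.dtype)
    for e in range(E):
        i = dst[e]
        j = src[e]
        for k in range(K):
            a = alpha[e, k]
            base = k * F
            for f in range(F):
                c = base + f
                out[i, c] += a * xk[j, c]
    return out


@njit(cache=True, fastmath=True)
def aggregate_bwd(g, alpha, xk, src, dst):
    E = src.shape[0]
    K = alpha.shape[1]
    C = xk.shape[1]
    F = C // K
    dalpha = np.zeros_like(alpha)
    dxk = np.zeros_like(xk)
    for e in range(E):
        i = dst[e]
        j = src[e]
        for k in range(K):
            a = alpha[e, k]
            base = k * F
            acc = 0.0
            for f in range(F):
                c = base + f
                gi = g[i, c]
                acc += gi * xk[j, c]
                dxk[j, c] += a * gi
            dalpha[e, k] = acc
    return dalpha, dxk
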