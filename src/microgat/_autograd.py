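"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the graph
attention model needs: broadcast arithmetic, 2-D matrix products,
elementwise nonlinearities, reductions, reshape/concatenate, gather and
segment-sum over precomputed index plans, and a fused segmented softmax
whose normalization is carried out in float64 regardless of the working
precision.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded operation graph in reverse topological order.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "SegmentPlan",
    "constant",
    "parameter",
    "matmul",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "softplus",
    "leaky_relu",
    "mish",
    "tsum",
    "reshape",
    "concat",
    "gather",
    "segment_sum",
    "segment_softmax",
]


class SegmentPlan:
    """Precomputed plan for row-wise reductions grouped by an integer key.

    The plan sorts the key array once; subsequent ``sum``/``max`` calls are
    contiguous ``reduceat`` reductions, which keeps scatter-style operations
    cheap inside the training loop.
    """

    __slots__ = ("idx", "n_segments", "order", "starts", "seg_ids", "_mat")

    def __init__(self, idx: np.ndarray, n_segments: int):
        idx = np.asarray(idx, dtype=np.int64)
        self.idx = idx
        self.n_segments = int(n_segments)
        order = np.argsort(idx, kind="stable")
        self.order = order
        sorted_idx = idx[order]
        if idx.size:
            starts = np.flatnonzero(
                np.concatenate(([True], sorted_idx[1:] != sorted_idx[:-1]))
            )
            self.starts = starts
            self.seg_ids = sorted_idx[starts]
        else:
            self.starts = np.zeros(0, dtype=np.int64)
            self.seg_ids = np.zeros(0, dtype=np.int64)
        self._mat = None

    def _matrix(self, dtype):
        # (n_segments, n_rows) indicator in CSR form; sparse @ dense is much
        # faster than reduceat on wide payloads
        if self._mat is None:
            self._mat = {}
        key = np.dtype(dtype).name
        if key not in self._mat:
            from scipy import sparse

            n_rows = self.idx.size
            indptr = np.zeros(self.n_segments + 1, dtype=np.int64)
            np.add.at(indptr, self.idx + 1, 1)
            np.cumsum(indptr, out=indptr)
            self._mat[key] = sparse.csr_matrix(
                (np.ones(n_rows, dtype=dtype), self.order, indptr),
                shape=(self.n_segments, n_rows),
            )
        return self._mat[key]

    def sum(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if self.idx.size == 0:
            return np.zeros((self.n_segments,) + x.shape[1:], dtype=x.dtype)
        if x.ndim == 1:
            out = np.zeros(self.n_segments, dtype=x.dtype)
            out[self.seg_ids] = np.add.reduceat(x[self.order], self.starts)
            return out
        shape = x.shape
        flat = np.ascontiguousarray(x.reshape(shape[0], -1))
        out = self._matrix(x.dtype).dot(flat)
        return out.reshape((self.n_segments,) + shape[1:])

    def max(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        out = np.zeros((self.n_segments,) + x.shape[1:], dtype=x.dtype)
        if self.idx.size:
            out[self.seg_ids] = np.maximum.reduceat(x[self.order], self.starts, axis=0)
        return out


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_bwd", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        bwd: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._bwd = bwd
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        """Accumulate gradients of ``self`` w.r.t. every reachable parent."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return _add(self, _wrap(other))

    def __radd__(self, other):
        return _add(_wrap(other), self)

    def __sub__(self, other):
        return _sub(self, _wrap(other))

    def __rsub__(self, other):
        return _sub(_wrap(other), self)

    def __mul__(self, other):
        return _mul(self, _wrap(other))

    def __rmul__(self, other):
        return _mul(_wrap(other), self)

    def __truediv__(self, other):
        return _div(self, _wrap(other))

    def __neg__(self):
        return _mul(self, _wrap(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    @property
    def T(self):
        return _transpose(self)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accum(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- arithmetic ----------------------------------------------------------


def _add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def _sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def _div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def _transpose(a: Tensor) -> Tensor:
    out_data = a.data.T

    def bwd(g):
        _accum(a, g.T)

    return Tensor(out_data, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return Tensor(out_data, (a, b), bwd)


# -- elementwise nonlinearities ------------------------------------------


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return Tensor(out_data, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bwd(g):
        _accum(a, g / a.data)

    return Tensor(out_data, (a,), bwd)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return Tensor(out_data, (a,), bwd)


def _sigmoid_data(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def sigmoid(a: Tensor) -> Tensor:
    out_data = _sigmoid_data(a.data)

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, (a,), bwd)


def softplus(a: Tensor) -> Tensor:
    out_data = np.logaddexp(np.array(0.0, dtype=a.data.dtype), a.data)

    def bwd(g):
        _accum(a, g * _sigmoid_data(a.data))

    return Tensor(out_data, (a,), bwd)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    x = a.data
    pos = x >= 0
    out_data = np.where(pos, x, x.dtype.type(slope) * x)

    def bwd(g):
        factor = np.where(pos, g.dtype.type(1.0), g.dtype.type(slope))
        _accum(a, g * factor)

    return Tensor(out_data, (a,), bwd)


def mish(a: Tensor) -> Tensor:
    """Mish activation, x * tanh(softplus(x)), fused at the NumPy level."""
    x = a.data
    sp = np.logaddexp(np.array(0.0, dtype=x.dtype), x)
    t = np.tanh(sp)
    out_data = x * t

    def bwd(g):
        grad = t + x * (1.0 - t * t) * _sigmoid_data(x)
        _accum(a, g * grad)

    return Tensor(out_data, (a,), bwd)


# -- shape / reductions ---------------------------------------------------


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape).copy())

    return Tensor(out_data, (a,), bwd)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return Tensor(out_data, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(out_data, tuple(tensors), bwd)


# -- graph-structured ops -------------------------------------------------


def gather(a: Tensor, idx: np.ndarray, plan: SegmentPlan) -> Tensor:
    """Row gather ``a[idx]``; ``plan`` must be a SegmentPlan over ``idx``
    with ``n_segments == a.shape[0]`` so the backward scatter is cheap."""
    out_data = a.data[idx]

    def bwd(g):
        _accum(a, plan.sum(g))

    return Tensor(out_data, (a,), bwd)


def segment_sum(a: Tensor, plan: SegmentPlan) -> Tensor:
    """Sum rows of ``a`` grouped by ``plan.idx``."""
    out_data = plan.sum(a.data)
    idx = plan.idx

    def bwd(g):
        _accum(a, g[idx])

    return Tensor(out_data, (a,), bwd)


def gatv2_scores(
    xq: Tensor,
    xk: Tensor,
    att: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    slope: float,
) -> Tensor:
    """Fused per-edge attention logits.

    ``scores[e, k] = att[k] . LeakyReLU(xq[dst_e] + xk[src_e])`` computed
    head-blockwise over the (K * F)-wide projections without materializing
    per-edge feature matrices.
    """
    from . import _kernels

    out_data = _kernels.edge_scores_fwd(xq.data, xk.data, att.data, src, dst, slope)

    def bwd(g):
        dxq, dxk, datt = _kernels.edge_scores_bwd(
            np.ascontiguousarray(g), xq.data, xk.data, att.data, src, dst, slope
        )
        _accum(xq, dxq)
        _accum(xk, dxk)
        _accum(att, datt)

    return Tensor(out_data, (xq, xk, att), bwd)


def attention_aggregate(
    alpha: Tensor, xk: Tensor, src: np.ndarray, dst: np.ndarray, n_nodes: int
) -> Tensor:
    """Fused attention-weighted neighbor sum per head block."""
    from . import _kernels

    out_data = _kernels.aggregate_fwd(alpha.data, xk.data, src, dst, n_nodes)

    def bwd(g):
        dalpha, dxk = _kernels.aggregate_bwd(
            np.ascontiguousarray(g), alpha.data, xk.data, src, dst
        )
        _accum(alpha, dalpha)
        _accum(xk, dxk)

    return Tensor(out_data, (alpha, xk), bwd)


def segment_softmax(
    scores: Tensor, plan: SegmentPlan, check: bool = False, check_atol: float = 1e-6
) -> Tensor:
    """Softmax of ``scores`` rows within segments defined by ``plan.idx``.

    The shift, exponentiation and normalization run in float64 no matter the
    working dtype, so each segment sums to one at double precision; the
    result is returned in the input dtype.  With ``check=True`` the
    normalization identity is asserted on every call (used as a test hook).
    """
    idx = plan.idx
    x = scores.data.astype(np.float64, copy=False)
    m = plan.max(x)
    ex = np.exp(x - m[idx])
    den = plan.sum(ex)
    alpha64 = ex / den[idx]
    if check:
        sums = plan.sum(alpha64)
        present = np.zeros(plan.n_segments, dtype=bool)
        present[plan.seg_ids] = True
        dev = np.abs(sums[present] - 1.0)
        if dev.size and dev.max() >= check_atol:
            raise AssertionError(
                f"segmented softmax failed to normalize: max |sum-1| = {dev.max():.3e}"
            )
    out_data = alpha64.astype(scores.dtype, copy=False)

    def bwd(g):
        gf = g.astype(np.float64, copy=False)
        inner = plan.sum(gf * alpha64)
        ds = alpha64 * (gf - inner[idx])
        _accum(scores, ds.astype(scores.dtype, copy=False))

    return Tensor(out_data, (scores,), bwd)
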