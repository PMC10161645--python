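"""Multi-head graph-attention encoder over the sample-similarity network.

Each layer computes, per attention head m, softmax-normalized coefficients

    alpha_ij = softmax_{j in N(i) u {i}} LeakyReLU(a^T [W h_i || W h_j])

restricted to the support of the normalized adjacency (edges plus
self-loops), aggregates ``h'_i = sum_j alpha_ij W h_j``, concatenates the
heads, and applies a LeakyReLU. By default the layer input is first
smoothed with the symmetric-normalized adjacency (``A_norm @ H``) so the
attention operates on degree-normalized neighborhoods; ``pure_gat``
disables the smoothing, leaving the textbook GAT layer.

Implementation notes: all heads of a layer are evaluated at once via
batched matmuls with a leading head axis, and the attention vector ``a``
is stored as its two halves (source and destination), so the pairwise
logit matrix is the rank-one sum ``f_src + f_dst^T`` — no concatenated
pair features are materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, constant, custom_op, parameter
from .graph import SimilarityGraph

__all__ = ["GATLayerParams", "attention_weights", "gat_layer", "encode", "init_stack"]


class _EdgeIndex:
    """Sparse support of the attention: edge list with row/column segments.

    Edges are stored in row-major order (``row_ptr`` gives per-row segment
    starts for ``reduceat``); ``perm`` re-sorts them by destination column
    for the scatter in the backward pass. Self-loops guarantee every row
    and column owns at least one edge.
    """

    def __init__(self, support: np.ndarray):
        support = np.asarray(support, dtype=bool)
        if not support.diagonal().all():
            raise ValueError("attention support must include all self-loops")
        self.n = support.shape[0]
        self.idx_i, self.idx_j = np.nonzero(support)
        self.row_ptr = np.searchsorted(self.idx_i, np.arange(self.n))
        self.perm = np.argsort(self.idx_j, kind="stable")
        self.col_ptr = np.searchsorted(self.idx_j[self.perm], np.arange(self.n))


def _edge_attention(HW: Tensor, f_src: Tensor, f_dst: Tensor, ei: _EdgeIndex,
                    att_slope: float) -> tuple[Tensor, np.ndarray]:
    """Fused masked-softmax attention + aggregation on the edge list.

    Computes, per head, ``out_i = sum_{j in N(i) u {i}} alpha_ij (HW)_j``
    with ``alpha = softmax_row(LeakyReLU(f_src_i + f_dst_j))`` evaluated
    only on the support edges. Returns the aggregated (M, N, F') Tensor
    and the edge-wise coefficients (M, E) for inspection.
    """
    HWd, fs, fd = HW.data, f_src.data[..., 0], f_dst.data[..., 0]
    ii, jj, rp = ei.idx_i, ei.idx_j, ei.row_ptr
    pre = fs[:, ii] + fd[:, jj]                               # (M, E)
    e = np.where(pre > 0, pre, att_slope * pre)
    rowmax = np.maximum.reduceat(e, rp, axis=1)
    ex = np.exp(e - rowmax[:, ii])
    denom = np.add.reduceat(ex, rp, axis=1)
    alpha = ex / denom[:, ii]
    contrib = alpha[:, :, None] * HWd[:, jj, :]               # (M, E, F')
    out = np.add.reduceat(contrib, rp, axis=1)                # (M, N, F')

    def backward(g):
        g_i = g[:, ii, :]
        d_alpha = np.einsum("mef,mef->me", g_i, HWd[:, jj, :])
        if HW.requires_grad:
            tmp = (alpha[:, :, None] * g_i)[:, ei.perm, :]
            HW._accum(np.add.reduceat(tmp, ei.col_ptr, axis=1))
        s = np.add.reduceat(alpha * d_alpha, rp, axis=1)
        d_pre = alpha * (d_alpha - s[:, ii]) * np.where(pre > 0, 1.0, att_slope)
        f_src._accum(np.add.reduceat(d_pre, rp, axis=1)[..., None])
        f_dst._accum(np.add.reduceat(d_pre[:, ei.perm], ei.col_ptr, axis=1)[..., None])

    return custom_op(out, (HW, f_src, f_dst), backward), alpha


@dataclass
class GATLayerParams:
    """One GAT layer: head-stacked W (M x F x F') and a = [a_src; a_dst]."""

    W: Tensor          # (M, F, F')
    a_src: Tensor      # (M, F', 1)
    a_dst: Tensor      # (M, F', 1)

    @property
    def n_heads(self) -> int:
        return self.W.shape[0]

    @property
    def out_width(self) -> int:
        return self.W.shape[0] * self.W.shape[2]

    def parameters(self) -> list[Tensor]:
        return [self.W, self.a_src, self.a_dst]

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, n_out: int, n_heads: int
             ) -> "GATLayerParams":
        # symmetric uniform, Glorot-scaled by fan-in/out
        lim_w = np.sqrt(6.0 / (n_in + n_out))
        lim_a = np.sqrt(6.0 / (n_out + 1))
        return cls(
            W=parameter(rng.uniform(-lim_w, lim_w, (n_heads, n_in, n_out))),
            a_src=parameter(rng.uniform(-lim_a, lim_a, (n_heads, n_out, 1))),
            a_dst=parameter(rng.uniform(-lim_a, lim_a, (n_heads, n_out, 1))),
        )


def attention_weights(H: Tensor, params: GATLayerParams, support: np.ndarray,
                      att_slope: float = 0.2) -> tuple[Tensor, Tensor]:
    """Attention coefficients, zero off-support; rows sum to 1 on support.

    Returns ``(alpha, projected)`` with shapes (M, N, N) and (M, N, F');
    ``projected = H @ W`` is reused by the aggregation step.
    """
    support = np.asarray(support, dtype=bool)
    if not support.diagonal().all():
        raise ValueError("attention support must include all self-loops")
    HW = H @ params.W                                   # (M, N, F')
    f_src = HW @ params.a_src                           # (M, N, 1)
    f_dst = HW @ params.a_dst                           # (M, N, 1)
    logits = (f_src + f_dst.swapaxes(-1, -2)).leaky_relu(att_slope)
    alpha = logits.masked_softmax(support, axis=-1)     # (M, N, N)
    return alpha, HW


def gat_layer(H: Tensor, support: np.ndarray | _EdgeIndex, params: GATLayerParams,
              att_slope: float = 0.2, act_slope: float = 0.01) -> Tensor:
    """One multi-head attention layer: aggregate, concatenate heads, LeakyReLU.

    Evaluates the attention sparsely on the support edges; the result is
    identical to the dense :func:`attention_weights` path.
    """
    ei = support if isinstance(support, _EdgeIndex) else _EdgeIndex(support)
    HW = H @ params.W                                   # (M, N, F')
    f_src = HW @ params.a_src                           # (M, N, 1)
    f_dst = HW @ params.a_dst
    out, _ = _edge_attention(HW, f_src, f_dst, ei, att_slope)
    n = out.shape[1]
    out = out.permute(1, 0, 2).reshape(n, params.out_width)  # head concatenation
    return out.leaky_relu(act_slope)


def encode(X: np.ndarray | Tensor, graph: SimilarityGraph,
           stack: list[GATLayerParams], pure_gat: bool = False,
           att_slope: float = 0.2, act_slope: float = 0.01) -> Tensor:
    """Compose the GAT stack over one omics view.

    Unless ``pure_gat``, each layer's input is pre-smoothed by the
    normalized adjacency (``A_norm @ H``) before attention.
    """
    if len(stack) < 1:
        raise ValueError("encoder needs at least one GAT layer")
    ei = _EdgeIndex(graph.support())
    A_norm = constant(graph.A_norm)
    H = X if isinstance(X, Tensor) else constant(X)
    for params in stack:
        if not pure_gat:
            H = A_norm @ H
        H = gat_layer(H, ei, params, att_slope=att_slope, act_slope=act_slope)
    return H


def init_stack(rng: np.random.Generator, n_in: int, hidden: tuple[int, ...],
               n_heads: int) -> list[GATLayerParams]:
    """Initialize L layers; ``hidden[l]`` is the per-head output width F'."""
    stack = []
    width = n_in
    for f_out in hidden:
        stack.append(GATLayerParams.init(rng, width, f_out, n_heads))
        width = f_out * n_heads
    return stack
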