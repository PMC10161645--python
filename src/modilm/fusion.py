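"""Cross-omics tensor fusion (VCDN).

For each sample the Q per-omics class-probability rows are combined into a
rank-one tensor of shape p^Q whose entry at (a_1, ..., a_Q) is
``prod_q phi^{(q)}_{i, a_q}``; because every row sums to 1, the tensor
entries sum to 1 as well. The tensor is flattened in C order (the last
view's class index varies fastest) and fed to a small fully connected
classifier — one hidden layer of width p^Q with LeakyReLU, then a linear
map to p logits — trained with an unweighted cross-entropy summed over
training samples.

The ablation without this classifier fuses by element-wise (Hadamard)
product of the Q probability rows, re-normalized per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, constant, parameter
from .heads import PROB_CLAMP

__all__ = ["CrossOmicsTensor", "cross_omics_tensor", "VCDNParams",
           "vcdn_forward", "vcdn_loss", "hadamard_fuse"]

#: refuse tensors larger than this (memory grows as p^Q)
MAX_TENSOR_SIZE = 10**6


@dataclass
class CrossOmicsTensor:
    """Flattened per-sample cross-omics probability tensors (N x p^Q)."""

    beta: Tensor
    n_classes: int
    n_views: int

    def tensor(self) -> np.ndarray:
        """Values reshaped to (N, p, ..., p) with one axis per view."""
        shape = (self.beta.shape[0],) + (self.n_classes,) * self.n_views
        return self.beta.data.reshape(shape)


def cross_omics_tensor(phis: list[Tensor | np.ndarray]) -> CrossOmicsTensor:
    """Outer product of the per-view probability rows, flattened to length p^Q."""
    if len(phis) < 1:
        raise ValueError("need at least one probability matrix")
    tensors = [phi if isinstance(phi, Tensor) else constant(phi) for phi in phis]
    p = tensors[0].shape[1]
    for t in tensors:
        if t.shape[1] != p:
            raise ValueError(
                f"class-count mismatch across omics: {t.shape[1]} != {p}")
    if p ** len(tensors) > MAX_TENSOR_SIZE:
        raise ValueError(
            f"cross-omics tensor size p^Q = {p ** len(tensors)} exceeds "
            f"{MAX_TENSOR_SIZE}; reduce the number of classes or views")
    n = tensors[0].shape[0]
    beta = tensors[0]
    for t in tensors[1:]:
        width = beta.shape[1]
        beta = (beta.reshape(n, width, 1) * t.reshape(n, 1, p)).reshape(n, width * p)
    return CrossOmicsTensor(beta=beta, n_classes=p, n_views=len(tensors))


@dataclass
class VCDNParams:
    """Fully connected classifier over the flattened cross-omics tensor."""

    weights: list[Tensor]
    biases: list[Tensor]
    act_slope: float = 0.01

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    @classmethod
    def init(cls, rng: np.random.Generator, n_classes: int, n_views: int,
             hidden: int | None = None, act_slope: float = 0.01) -> "VCDNParams":
        n_in = n_classes ** n_views
        h = n_in if hidden is None else int(hidden)
        weights, biases = [], []
        for a, b in ((n_in, h), (h, n_classes)):
            lim = np.sqrt(6.0 / (a + b))
            weights.append(parameter(rng.uniform(-lim, lim, (a, b))))
            biases.append(parameter(np.zeros((1, b))))
        return cls(weights=weights, biases=biases, act_slope=act_slope)


def vcdn_forward(beta: Tensor | np.ndarray, params: VCDNParams) -> Tensor:
    """Logits (N x p) from flattened tensors."""
    H = beta if isinstance(beta, Tensor) else constant(beta)
    H = (H @ params.weights[0] + params.biases[0]).leaky_relu(params.act_slope)
    z = H @ params.weights[1] + params.biases[1]
    if not np.isfinite(z.data).all():
        raise FloatingPointError("non-finite VCDN logits")
    return z


def vcdn_loss(z: Tensor, y: np.ndarray,
              sample_mask: np.ndarray | None = None) -> Tensor:
    """Unweighted cross-entropy of softmax(z) against y, summed over samples."""
    y = np.asarray(y, dtype=int)
    if sample_mask is None:
        sample_mask = np.ones(len(y), dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    p = z.shape[1]
    onehot = np.zeros((len(y), p))
    onehot[np.arange(len(y)), y] = 1.0
    onehot *= sample_mask[:, None]
    probs = z.softmax(axis=1)
    return -(constant(onehot) * probs.log(clamp=PROB_CLAMP)).sum()


def hadamard_fuse(phis: list[np.ndarray]) -> np.ndarray:
    """Element-wise product of per-view probability rows, re-normalized.

    The argmax is invariant to the normalization; it is applied so the
    output is a valid probability row.
    """
    prod = np.ones_like(np.asarray(phis[0], dtype=float))
    for phi in phis:
        prod = prod * np.asarray(phi, dtype=float)
    total = prod.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return prod / total
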