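"""Per-omics MLP heads and the class-frequency-weighted cross-entropy.

Each omics encoding is mapped through a small MLP (LeakyReLU hidden
layers, linear output) and a final softmax to a class-probability row phi
per sample. The per-omics training loss weights each sample's
cross-entropy by its class's empirical frequency S_rho = count(rho)/N in
the training labels — as specified, this up-weights majority classes; the
``inverse_frequency`` option re-normalizes 1/S_rho for the conventional
imbalance correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._autodiff import Tensor, constant, parameter

__all__ = ["MLPParams", "mlp_forward", "class_frequency_weights", "weighted_ce",
           "ClassWeights"]

#: floor applied to predicted probabilities inside log
PROB_CLAMP = 1e-12


@dataclass
class MLPParams:
    """Weights of one head: t hidden layers then a linear map to p logits."""

    weights: list[Tensor]
    biases: list[Tensor]
    act_slope: float = 0.01

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, hidden: tuple[int, ...],
             n_classes: int, act_slope: float = 0.01) -> "MLPParams":
        widths = [n_in, *hidden, n_classes]
        weights, biases = [], []
        for a, b in zip(widths[:-1], widths[1:]):
            lim = np.sqrt(6.0 / (a + b))
            weights.append(parameter(rng.uniform(-lim, lim, (a, b))))
            biases.append(parameter(np.zeros((1, b))))
        return cls(weights=weights, biases=biases, act_slope=act_slope)


def mlp_forward(Y: np.ndarray | Tensor, params: MLPParams) -> Tensor:
    """Map encodings to class-probability rows (softmax output).

    With no hidden layers this is a linear map followed by softmax; hidden
    layers use LeakyReLU activations.
    """
    H = Y if isinstance(Y, Tensor) else constant(Y)
    last = len(params.weights) - 1
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        H = H @ w + b
        if i < last:
            H = H.leaky_relu(params.act_slope)
        if not np.isfinite(H.data).all():
            raise FloatingPointError(f"non-finite activations at MLP layer {i}")
    return H.softmax(axis=1)


@dataclass
class ClassWeights:
    """Empirical class frequencies S_rho = count(rho)/N over training labels."""

    S_vec: np.ndarray
    counts: np.ndarray

    def per_sample(self, y: np.ndarray) -> np.ndarray:
        return self.S_vec[np.asarray(y, dtype=int)]


def class_frequency_weights(y: np.ndarray, n_classes: int | None = None,
                            inverse: bool = False) -> ClassWeights:
    """Class weights from training labels; every class must occur.

    ``inverse`` replaces S_rho by (1/S_rho) re-normalized to sum to 1.
    """
    y = np.asarray(y, dtype=int)
    p = int(n_classes) if n_classes is not None else int(y.max()) + 1
    counts = np.bincount(y, minlength=p)
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"class {empty} has no training samples")
    n = len(y)
    # exact rationals first so the weights sum to 1 exactly
    fracs = [Fraction(int(c), n) for c in counts]
    if inverse:
        inv = [1 / f for f in fracs]
        tot = sum(inv)
        fracs = [f / tot for f in inv]
    S = np.array([float(f) for f in fracs])
    return ClassWeights(S_vec=S, counts=counts)


def weighted_ce(phis: list[Tensor | np.ndarray], y: np.ndarray,
                weights: ClassWeights,
                sample_mask: np.ndarray | None = None) -> Tensor:
    """Class-frequency-weighted cross-entropy summed over omics views.

    ``L = -sum_q (1/N) sum_i S_rho(i) log phi^{(q)}_{i, y_i}`` over the
    samples selected by ``sample_mask`` (training nodes); N is the number
    of selected samples. Probabilities are clamped at 1e-12 with a warning.
    """
    y = np.asarray(y, dtype=int)
    if sample_mask is None:
        sample_mask = np.ones(len(y), dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    n = int(sample_mask.sum())
    if n == 0:
        raise ValueError("no training samples selected")
    p = len(weights.S_vec)
    onehot = np.zeros((len(y), p))
    onehot[np.arange(len(y)), y] = 1.0
    onehot *= sample_mask[:, None]
    coef = constant(onehot * weights.per_sample(y)[:, None] / n)

    total: Tensor | None = None
    for phi in phis:
        phi_t = phi if isinstance(phi, Tensor) else constant(phi)
        true_p = phi_t.data[sample_mask, y[sample_mask]]
        if (true_p < PROB_CLAMP).any():
            warnings.warn("predicted probability at true class clamped at 1e-12",
                          RuntimeWarning, stacklevel=2)
        term = -(coef * phi_t.log(clamp=PROB_CLAMP)).sum()
        total = term if total is None else total + term
    return total
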