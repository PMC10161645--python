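"""Sample-similarity networks from omics matrices.

Nodes are samples; edge weights are cosine similarities. The retention
threshold theta is chosen so that the average number of retained ordered
pairs per node — counting the self-pair, whose similarity is 1 — is at
least a target k. The adjacency keeps the similarity value on surviving
edges (weighted graph, zero diagonal), and the network enters the encoder
through the symmetric normalization
``A_norm = D^{-1/2} (A + I) D^{-1/2}`` with D the degree matrix of A + I.

Ties at theta are all retained, so the achieved mean degree may overshoot
k by the size of the tie class; the selection is deterministic and
independent of sample order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

__all__ = [
    "cosine_similarity_matrix",
    "select_threshold",
    "build_adjacency",
    "normalize_adjacency",
    "SimilarityGraph",
    "attach_samples",
]


def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of sample rows; rejects zero-norm rows."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"sample row {bad[0]} has zero norm; cosine undefined")
    S = _sk_cosine(X)
    return (S + S.T) / 2.0


def select_threshold(S: np.ndarray, k: int) -> float:
    """Largest theta retaining on average >= k ordered pairs per node.

    Counts self-pairs, so theta is the (k*N)-th largest value of the full
    N^2 ordered-pair similarity multiset (diagonal included).
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}] for {n} samples")
    budget = k * n
    if budget > S.size:
        raise ValueError(f"k*N = {budget} exceeds the number of ordered pairs {S.size}")
    flat = np.sort(S, axis=None)[::-1]
    return float(flat[budget - 1])


def build_adjacency(S: np.ndarray, theta: float) -> np.ndarray:
    """Weighted adjacency: A_ij = S_ij where i != j and S_ij >= theta, else 0."""
    S = np.asarray(S, dtype=float)
    A = np.where(S >= theta, S, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization of A + I by its degree matrix."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)  # self-loop guarantees d >= 1
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class SimilarityGraph:
    """Cosine-similarity sample network for one omics view."""

    S: np.ndarray
    theta: float
    k: int
    A: np.ndarray
    A_norm: np.ndarray

    @classmethod
    def from_matrix(cls, X: np.ndarray, k: int) -> "SimilarityGraph":
        S = cosine_similarity_matrix(X)
        theta = select_threshold(S, k)
        A = build_adjacency(S, theta)
        return cls(S=S, theta=theta, k=k, A=A, A_norm=normalize_adjacency(A))

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]

    @property
    def mean_degree(self) -> float:
        """Achieved mean retained ordered pairs per node, self-pair included."""
        return float((self.S >= self.theta).sum() / self.n_nodes)

    def support(self) -> np.ndarray:
        """Boolean attention support: edges of A plus self-loops."""
        return (self.A != 0) | np.eye(self.n_nodes, dtype=bool)

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.A, 1))
        return [(int(a), int(b), float(self.A[a, b])) for a, b in zip(i, j)]

    def save_edge_list(self, path) -> None:
        """Tab-separated weighted edge list (i, j, weight), upper triangle."""
        with open(path, "w") as fh:
            fh.write(f"# theta={self.theta}\tk={self.k}\tmean_degree={self.mean_degree}\n")
            fh.write("i\tj\tweight\n")
            for i, j, w in self.edge_list():
                fh.write(f"{i}\t{j}\t{w}\n")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edge_list())
        return g


def attach_samples(X_train: np.ndarray, X_new: np.ndarray, theta: float, k: int
                   ) -> SimilarityGraph:
    """Joint graph over train + new samples using a previously selected theta.

    New samples are attached with the training threshold rather than
    re-selecting it, so the training geometry is preserved at predict time.
    """
    X = np.vstack([np.asarray(X_train, float), np.asarray(X_new, float)])
    S = cosine_similarity_matrix(X)
    A = build_adjacency(S, theta)
    return SimilarityGraph(S=S, theta=theta, k=k, A=A,
                           A_norm=normalize_adjacency(A))
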