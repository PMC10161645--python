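"""Synthetic multi-omics data with class-dependent shared structure.

The generator emulates matched multi-view molecular profiles: each sample
carries a class label and an individual latent vector shared across views;
within each view a subset of "informative" features receives a
class-specific mean shift of size ``delta`` (in units of the noise
standard deviation) plus a loading of the shared latent, while the
remaining features are pure Gaussian noise. ``delta = 0`` therefore
contains no class signal anywhere (negative control), and the latent term
induces cross-view correlation that is independent of the class.

Class counts are allocated deterministically from the proportions by the
largest-remainder method, so count patterns like 169/182 (n=351) or
10/16/18/8 (n=52) are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from .preprocess import OmicsMatrix

__all__ = ["SimSpec", "SimulatedDataset", "generate_dataset", "split_dataset",
           "allocate_class_counts"]

_DEFAULT_TAGS = ("miRNA", "mRNA", "meth")


@dataclass
class SimSpec:
    """Study design of one synthetic multi-omics dataset.

    delta is the class-separation effect size: informative features get
    class means drawn from N(0, (delta * noise_sd)^2). latent_scale sets
    the strength of the class-independent latent shared across views
    (cross-view correlation), in units of noise_sd.
    """

    n_samples: int = 200
    n_classes: int = 3
    proportions: tuple[float, ...] | None = None
    n_views: int = 3
    n_features: tuple[int, ...] = (100, 200, 150)
    n_informative: tuple[int, ...] = (20, 30, 25)
    delta: float = 3.0
    noise_sd: float = 1.0
    latent_dim: int = 5
    latent_scale: float = 0.5
    beta_views: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.proportions is not None:
            if len(self.proportions) != self.n_classes:
                raise ValueError("proportions length must equal n_classes")
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")
        if len(self.n_features) != self.n_views or len(self.n_informative) != self.n_views:
            raise ValueError("n_features and n_informative must have one entry per view")
        for d, m in zip(self.n_features, self.n_informative):
            if m > d:
                raise ValueError("n_informative cannot exceed n_features")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class for ANOVA")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    views: list[OmicsMatrix]
    y: np.ndarray
    class_names: list[str]
    truth: dict = field(default_factory=dict)


def allocate_class_counts(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder allocation of n samples to classes."""
    shares = np.asarray(proportions, dtype=float) * n
    counts = np.floor(shares).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(shares - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_dataset(spec: SimSpec) -> SimulatedDataset:
    """Draw one dataset; identical specs (including seed) give identical data."""
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_classes, spec.n_samples
    props = spec.proportions or tuple([1.0 / p] * p)
    counts = allocate_class_counts(n, props)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples; adjust proportions")
    y = np.repeat(np.arange(p), counts)
    rng.shuffle(y)

    # class-independent per-sample latent, shared across views
    u = rng.standard_normal((n, spec.latent_dim))

    views: list[OmicsMatrix] = []
    truth: dict = {"informative": [], "class_means": [], "latent": u, "spec": spec.to_dict()}
    sample_ids = [f"S{i:04d}" for i in range(n)]
    for q in range(spec.n_views):
        d, m = spec.n_features[q], spec.n_informative[q]
        tag = _DEFAULT_TAGS[q] if q < len(_DEFAULT_TAGS) else "other"
        info_idx = np.sort(rng.choice(d, size=m, replace=False))
        mu = rng.standard_normal((p, m)) * spec.delta * spec.noise_sd
        loadings = rng.standard_normal((spec.latent_dim, m)) / np.sqrt(spec.latent_dim)

        X = rng.standard_normal((n, d)) * spec.noise_sd
        X[:, info_idx] += mu[y] + spec.latent_scale * spec.noise_sd * (u @ loadings)
        if q in spec.beta_views:
            X = 1.0 / (1.0 + np.exp(-X))  # squash into (0, 1), methylation-like
        views.append(OmicsMatrix(X, sample_ids,
                                 [f"{tag}_f{j:05d}" for j in range(d)], tag))
        truth["informative"].append(info_idx)
        truth["class_means"].append(mu)

    names = [f"class{c}" for c in range(p)]
    return SimulatedDataset(views=views, y=y, class_names=names, truth=truth)


def split_dataset(y: np.ndarray, fraction: float = 0.7, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test indices; ``fraction`` is the training share."""
    y = np.asarray(y)
    n = len(y)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return np.arange(n), np.array([], dtype=int)
    _, cls_counts = np.unique(y, return_counts=True)
    if (cls_counts < 2).any():
        raise ValueError("every class needs at least 2 samples to stratify")
    train_idx, test_idx = train_test_split(
        np.arange(n), train_size=fraction, stratify=y, random_state=int(seed))
    return np.sort(train_idx), np.sort(test_idx)
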