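"""MODILM classifier: per-omics GAT encoders + MLP heads fused by a VCDN.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and supports two usage modes:

* **transductive** — pass all samples to ``fit`` with label ``-1`` for
  unlabeled nodes (the LabelPropagation convention). Unlabeled nodes sit
  in the similarity graphs and receive embeddings but contribute nothing
  to any loss; ``predict()`` with no argument returns their labels.
* **inductive** — fit on labeled samples only; ``predict(X_new)`` attaches
  new samples to each view's graph using the stored threshold theta and
  runs the trained forward pass.

Training minimizes, with Adam, the sum over views of the class-frequency-
weighted cross-entropy of each head plus ``gamma`` times the VCDN
cross-entropy, after a per-view pre-training phase of the heads alone.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor, constant, parameter
from . import fusion, gat, heads
from .graph import SimilarityGraph, attach_samples

__all__ = ["MODILMClassifier"]


def _as_views(X) -> list[np.ndarray]:
    if isinstance(X, (list, tuple)):
        views = [np.asarray(v, dtype=float) for v in X]
    else:
        views = [np.asarray(X, dtype=float)]
    n = views[0].shape[0]
    for v in views:
        if v.ndim != 2 or v.shape[0] != n:
            raise ValueError("all omics views must be 2-D with the same sample count")
        if not np.isfinite(v).all():
            raise ValueError("omics views must be finite; clean the data first")
    return views


class MODILMClassifier(ClassifierMixin, BaseEstimator):
    """Multi-omics graph-attention classifier with cross-omics tensor fusion.

    Parameters
    ----------
    k : int or sequence of int
        Target mean retained edges per node (self-pair included) for the
        similarity graph of each view; 2-10 is the sensible range.
    gat_hidden : tuple of int
        Per-head output width F' of each GAT layer; the tuple length is the
        number of GAT layers (default 2).
    n_heads : int
        Attention heads per GAT layer (default 8); head outputs concatenate.
    mlp_hidden : tuple of int
        Hidden widths of each per-omics MLP head (default 2 hidden layers).
    lr : float
        Adam learning rate (default 1e-4).
    gamma : float
        Trade-off between the per-omics losses and the VCDN loss (default 1).
    pretrain_epochs, joint_epochs : int
        Per-omics pre-training steps, then joint steps over the total loss.
    ablation : {'full', 'no_gat', 'no_vcdn'}
        'no_gat' replaces the GAT stack with a single linear map (no graph);
        'no_vcdn' drops the fusion network and predicts from the Hadamard
        product of the per-view probability rows.
    pure_gat : bool
        Skip the normalized-adjacency input smoothing inside each GAT layer.
    inverse_frequency : bool
        Use re-normalized inverse class frequencies in the weighted loss.
    vcdn_hidden : int or None
        Hidden width of the fusion classifier (None -> p^Q).
    att_slope, act_slope : float
        LeakyReLU slopes inside attention (0.2) and between layers (0.01).
    seed : int
        Seeds parameter initialization; the whole fit is deterministic.
    """

    def __init__(self, k=5, gat_hidden=(32, 8), n_heads=8, mlp_hidden=(64, 32),
                 lr=1e-4, gamma=1.0, pretrain_epochs=300, joint_epochs=600,
                 ablation="full", pure_gat=False, inverse_frequency=False,
                 vcdn_hidden=None, att_slope=0.2, act_slope=0.01, seed=0):
        self.k = k
        self.gat_hidden = gat_hidden
        self.n_heads = n_heads
        self.mlp_hidden = mlp_hidden
        self.lr = lr
        self.gamma = gamma
        self.pretrain_epochs = pretrain_epochs
        self.joint_epochs = joint_epochs
        self.ablation = ablation
        self.pure_gat = pure_gat
        self.inverse_frequency = inverse_frequency
        self.vcdn_hidden = vcdn_hidden
        self.att_slope = att_slope
        self.act_slope = act_slope
        self.seed = seed

    # -- forward pass --------------------------------------------------

    def _encode_view(self, q: int, X: np.ndarray, graph: SimilarityGraph | None
                     ) -> Tensor:
        if self.ablation == "no_gat":
            return (constant(X) @ self.linear_maps_[q]).leaky_relu(self.act_slope)
        return gat.encode(X, graph, self.gat_stacks_[q], pure_gat=self.pure_gat,
                          att_slope=self.att_slope, act_slope=self.act_slope)

    def _forward_phis(self, views: list[np.ndarray],
                      graphs: list[SimilarityGraph | None]) -> list[Tensor]:
        return [heads.mlp_forward(self._encode_view(q, X, g), self.mlp_params_[q])
                for q, (X, g) in enumerate(zip(views, graphs))]

    def _fuse(self, phis: list[Tensor]) -> Tensor:
        beta = fusion.cross_omics_tensor(phis).beta
        z = fusion.vcdn_forward(beta, self.vcdn_params_)
        return z.softmax(axis=1)

    def _predict_proba_from_phis(self, phis: list[Tensor]) -> np.ndarray:
        if self.ablation == "no_vcdn":
            return fusion.hadamard_fuse([phi.data for phi in phis])
        return self._fuse(phis).data

    # -- training ------------------------------------------------------

    def fit(self, X, y) -> "MODILMClassifier":
        views = _as_views(X)
        y = np.asarray(y)
        if y.shape[0] != views[0].shape[0]:
            raise ValueError("label length must match the sample count")
        labeled = y != -1
        if not labeled.any():
            raise ValueError("need at least one labeled sample")
        self.classes_, y_enc = np.unique(y[labeled], return_inverse=True)
        y_all = np.zeros(len(y), dtype=int)
        y_all[labeled] = y_enc
        p = len(self.classes_)
        if p < 2:
            raise ValueError("need at least 2 classes")
        Q = len(views)
        if self.ablation not in ("full", "no_gat", "no_vcdn"):
            raise ValueError(f"unknown ablation mode {self.ablation!r}")
        ks = list(self.k) if isinstance(self.k, (list, tuple)) else [self.k] * Q

        rng = np.random.default_rng(self.seed)
        n_layers = len(self.gat_hidden)
        if n_layers not in (2, 3, 4):
            import warnings

            warnings.warn(f"{n_layers} GAT layer(s) is outside the explored "
                          "range {2,3,4}", UserWarning, stacklevel=2)

        # graphs (not needed for the linear-map ablation)
        if self.ablation == "no_gat":
            self.graphs_ = [None] * Q
        else:
            self.graphs_ = [SimilarityGraph.from_matrix(v, kq)
                            for v, kq in zip(views, ks)]
        self.theta_per_view_ = [g.theta if g else None for g in self.graphs_]

        # parameters
        enc_width = self.gat_hidden[-1] * self.n_heads
        per_view_params: list[list[Tensor]] = []
        self.gat_stacks_, self.linear_maps_, self.mlp_params_ = [], [], []
        for v in views:
            d = v.shape[1]
            if self.ablation == "no_gat":
                lim = np.sqrt(6.0 / (d + enc_width))
                lin = parameter(rng.uniform(-lim, lim, (d, enc_width)))
                self.linear_maps_.append(lin)
                view_params = [lin]
            else:
                stack = gat.init_stack(rng, d, tuple(self.gat_hidden), self.n_heads)
                self.gat_stacks_.append(stack)
                view_params = [t for layer in stack for t in layer.parameters()]
            head = heads.MLPParams.init(rng, enc_width, tuple(self.mlp_hidden), p,
                                        act_slope=self.act_slope)
            self.mlp_params_.append(head)
            per_view_params.append(view_params + head.parameters())

        if self.ablation == "no_vcdn":
            self.vcdn_params_ = None
        else:
            self.vcdn_params_ = fusion.VCDNParams.init(
                rng, p, Q, hidden=self.vcdn_hidden, act_slope=self.act_slope)

        self.class_weights_ = heads.class_frequency_weights(
            y_all[labeled], n_classes=p, inverse=self.inverse_frequency)

        # Eq.-style bookkeeping: losses only ever touch labeled nodes
        mask = labeled
        self.pretrain_losses_: list[float] = []
        self.joint_losses_: list[float] = []

        def check(value: float, phase: str) -> None:
            if not np.isfinite(value):
                hist = self.pretrain_losses_ if phase == "pretrain" else self.joint_losses_
                last = hist[-1] if hist else None
                raise RuntimeError(
                    f"{phase} loss diverged (last finite loss: {last})")

        flat_view_params = [t for ps in per_view_params for t in ps]
        if self.pretrain_epochs > 0:
            opt = Adam(flat_view_params, lr=self.lr)
            for _ in range(self.pretrain_epochs):
                opt.zero_grad()
                phis = self._forward_phis(views, self.graphs_)
                loss = heads.weighted_ce(phis, y_all, self.class_weights_, mask)
                check(loss.data.item(), "pretrain")
                self.pretrain_losses_.append(loss.data.item())
                loss.backward()
                opt.step()

        all_params = list(flat_view_params)
        if self.vcdn_params_ is not None:
            all_params += self.vcdn_params_.parameters()
        opt = Adam(all_params, lr=self.lr)
        for _ in range(self.joint_epochs):
            opt.zero_grad()
            phis = self._forward_phis(views, self.graphs_)
            loss = heads.weighted_ce(phis, y_all, self.class_weights_, mask)
            if self.vcdn_params_ is not None and self.gamma != 0:
                beta = fusion.cross_omics_tensor(phis).beta
                z = fusion.vcdn_forward(beta, self.vcdn_params_)
                loss = loss + self.gamma * fusion.vcdn_loss(z, y_all, mask)
            check(loss.data.item(), "joint")
            self.joint_losses_.append(loss.data.item())
            loss.backward()
            opt.step()

        # cache fitted-node outputs for the transductive read-out
        phis = self._forward_phis(views, self.graphs_)
        self.phi_per_view_ = [phi.data for phi in phis]
        self.proba_ = self._predict_proba_from_phis(phis)
        self.labels_ = self.classes_[np.argmax(self.proba_, axis=1)]
        self.X_fit_ = views
        self.y_fit_ = y
        self.n_views_ = Q
        self.ks_ = ks
        return self

    # -- inference -----------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "proba_"):
            raise RuntimeError("MODILMClassifier is not fitted")

    def predict_proba(self, X=None) -> np.ndarray:
        """Class probabilities; ``X=None`` returns the fitted nodes' rows."""
        self._check_fitted()
        if X is None:
            return self.proba_
        views = _as_views(X)
        if len(views) != self.n_views_:
            raise ValueError(f"expected {self.n_views_} omics views")
        n_train = self.X_fit_[0].shape[0]
        if self.ablation == "no_gat":
            graphs = [None] * self.n_views_
            joint = views
        else:
            graphs = [attach_samples(tr, new, theta, kq)
                      for tr, new, theta, kq in
                      zip(self.X_fit_, views, self.theta_per_view_, self.ks_)]
            joint = [np.vstack([tr, new]) for tr, new in zip(self.X_fit_, views)]
        phis = self._forward_phis(joint, graphs)
        proba = self._predict_proba_from_phis(phis)
        return proba if self.ablation == "no_gat" else proba[n_train:]

    def predict(self, X=None) -> np.ndarray:
        self._check_fitted()
        if X is None:
            return self.labels_
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
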