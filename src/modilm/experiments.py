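"""End-to-end experiment pipeline: preprocess, fit transductively, evaluate.

This is the orchestration layer the CLI and the validation experiments
share. Feature filters are fit on training samples only; the classifier is
fit transductively (test nodes in the graphs with label -1) and metrics
are computed on the held-out nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import MODILMClassifier
from .metrics import MetricsRecord, evaluate_metrics
from .preprocess import OmicsMatrix, OmicsPreprocessor
from .simulate import SimSpec, generate_dataset, split_dataset

__all__ = ["ExperimentResult", "run_experiment", "run_synthetic_experiment"]

#: desk-scale preprocessing defaults per view tag
DEFAULT_VARIANCE_THRESHOLDS = {"miRNA": 0.0, "mRNA": 0.1, "meth": 0.001, "other": 0.0}


@dataclass
class ExperimentResult:
    metrics: MetricsRecord
    model: MODILMClassifier
    y_pred: np.ndarray
    proba: np.ndarray
    test_idx: np.ndarray
    preprocessors: list[OmicsPreprocessor] | None = None
    log: dict = field(default_factory=dict)


def run_experiment(views: list[OmicsMatrix] | list[np.ndarray], y: np.ndarray,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   anova_top_j: int = 50,
                   variance_thresholds: dict[str, float] | None = None,
                   preprocess: bool = True,
                   **estimator_params) -> ExperimentResult:
    """Filter each view on the training rows, fit transductively, evaluate.

    ``estimator_params`` are forwarded to :class:`MODILMClassifier`.
    """
    y = np.asarray(y)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    vt = dict(DEFAULT_VARIANCE_THRESHOLDS)
    if variance_thresholds:
        vt.update(variance_thresholds)

    mats: list[np.ndarray] = []
    kept: list[int] = []
    preps: list[OmicsPreprocessor] | None = [] if preprocess else None
    for v in views:
        tag = v.omics_tag if isinstance(v, OmicsMatrix) else "other"
        X = v.values if isinstance(v, OmicsMatrix) else np.asarray(v, float)
        if preprocess:
            prep = OmicsPreprocessor(variance_threshold=vt.get(tag, 0.0),
                                     anova_rule="top", anova_top_j=anova_top_j)
            prep.fit(X[train_idx], y[train_idx])
            X = prep.transform(X)
            preps.append(prep)
        mats.append(X)
        kept.append(X.shape[1])

    y_masked = y.copy()
    if test_idx.size:
        y_masked[test_idx] = -1
    model = MODILMClassifier(**estimator_params)
    model.fit(mats, y_masked)

    y_pred = model.predict()
    proba = model.predict_proba()
    if test_idx.size:
        metrics = evaluate_metrics(y[test_idx], y_pred[test_idx], proba[test_idx])
    else:
        metrics = evaluate_metrics(y[train_idx], y_pred[train_idx], proba[train_idx])
    log = {
        "kept_features": kept,
        "theta_per_view": model.theta_per_view_,
        "final_joint_loss": model.joint_losses_[-1] if model.joint_losses_ else None,
        "final_pretrain_loss": model.pretrain_losses_[-1] if model.pretrain_losses_ else None,
    }
    return ExperimentResult(metrics=metrics, model=model, y_pred=y_pred,
                            proba=proba, test_idx=test_idx, preprocessors=preps,
                            log=log)


def run_synthetic_experiment(spec: SimSpec | None = None, seed: int = 0,
                             train_fraction: float = 0.7,
                             view_subset: tuple[int, ...] | None = None,
                             anova_top_j: int = 50,
                             **estimator_params) -> ExperimentResult:
    """Generate a dataset from ``spec`` (reseeded with ``seed``), split, run.

    ``view_subset`` selects omics views by index for the combination
    experiments; estimator defaults are used unless overridden.
    """
    spec = spec or SimSpec()
    spec = SimSpec(**{**spec.to_dict(), "seed": seed})
    data = generate_dataset(spec)
    views = data.views
    if view_subset is not None:
        views = [views[q] for q in view_subset]
    train_idx, test_idx = split_dataset(data.y, fraction=train_fraction, seed=seed)
    estimator_params.setdefault("seed", seed)
    return run_experiment(views, data.y, train_idx, test_idx,
                          anova_top_j=anova_top_j, **estimator_params)
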