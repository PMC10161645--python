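"""Omics matrix I/O and feature filtering.

One omics view is a samples x features real matrix (expression or
methylation beta values) with shared sample identifiers across views.
Three filters are applied per view, fit on training samples only:

1. cleaning — drop feature columns containing missing/INF markers, and
   columns whose fraction of exact zeros exceeds a limit (default 10%);
2. a variance floor (unbiased sample variance, n-1 denominator);
3. a one-way ANOVA F-score filter against the class labels, with three
   built-in rules: drop features with F == 0, keep features with F below a
   printed threshold, or keep the top-J features by F (the recommended
   default for discriminative selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "FilterReport",
    "clean_matrix",
    "variance_filter",
    "anova_f_scores",
    "anova_filter",
    "read_omics_csv",
    "read_labels",
    "OmicsPreprocessor",
]

#: cell contents recognized as missing; anything else non-numeric is an error
MISSING_MARKERS = {"", "NA", "NaN", "nan", "INF", "-INF"}


@dataclass
class OmicsMatrix:
    """One omics view: real matrix with sample/feature identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_tag: str = "other"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature identifiers")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, mask: np.ndarray) -> "OmicsMatrix":
        mask = np.asarray(mask, dtype=bool)
        return OmicsMatrix(
            self.values[:, mask],
            self.sample_ids,
            [f for f, m in zip(self.feature_ids, mask) if m],
            self.omics_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="sample_id")


@dataclass
class FilterReport:
    """Per-feature audit of the filtering pipeline for one omics view."""

    feature_ids: list[str]
    zero_fraction: np.ndarray | None = None
    variance: np.ndarray | None = None
    f_score: np.ndarray | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def add_stage(self, name: str, keep: np.ndarray) -> None:
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (len(self.feature_ids),):
            raise ValueError("keep-mask length must equal the pre-filter feature count")
        if self.masks:
            prev = self.combined_mask()
            keep = keep & prev  # composed masks are monotone
        self.masks[name] = keep

    def combined_mask(self) -> np.ndarray:
        mask = np.ones(len(self.feature_ids), dtype=bool)
        for m in self.masks.values():
            mask &= m
        return mask

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {}
        if self.zero_fraction is not None:
            cols["zero_fraction"] = self.zero_fraction
        if self.variance is not None:
            cols["variance"] = self.variance
        if self.f_score is not None:
            cols["anova_f"] = self.f_score
        for name, m in self.masks.items():
            cols[f"keep_{name}"] = m
        return pd.DataFrame(cols, index=self.feature_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# filters


def clean_matrix(raw: OmicsMatrix, zero_fraction_limit: float = 0.10
                 ) -> tuple[OmicsMatrix, FilterReport]:
    """Drop features containing NaN/INF, then features with too many zeros.

    ``zero_fraction_limit`` is the maximum tolerated fraction of exact-zero
    entries per feature (strictly-greater fractions are dropped).
    """
    if not 0.0 <= zero_fraction_limit <= 1.0:
        raise ValueError("zero_fraction_limit must be in [0, 1]")
    X = raw.values
    finite = np.isfinite(X).all(axis=0)
    zero_frac = np.zeros(X.shape[1])
    with np.errstate(invalid="ignore"):
        zero_frac[finite] = (X[:, finite] == 0).mean(axis=0)
    keep = finite & (zero_frac <= zero_fraction_limit)

    report = FilterReport(list(raw.feature_ids), zero_fraction=zero_frac)
    report.add_stage("finite", finite)
    report.add_stage("zero_fraction", finite & (zero_frac <= zero_fraction_limit))
    if not keep.any():
        raise ValueError(f"empty matrix after cleaning omics '{raw.omics_tag}'")
    return raw.select_features(keep), report


def variance_filter(m: OmicsMatrix, threshold: float
                    ) -> tuple[OmicsMatrix, FilterReport]:
    """Drop features whose unbiased sample variance is <= ``threshold``.

    A threshold of 0 keeps every feature with nonzero variance; negative
    thresholds are rejected.
    """
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    var = m.values.var(axis=0, ddof=1)
    keep = var > threshold if threshold > 0 else np.ones(m.n_features, dtype=bool)
    report = FilterReport(list(m.feature_ids), variance=var)
    report.add_stage("variance", keep)
    if not keep.any():
        raise ValueError(
            f"no features survive variance threshold {threshold} for omics "
            f"'{m.omics_tag}'; try a lower threshold"
        )
    return m.select_features(keep), report


def anova_f_scores(values: np.ndarray | OmicsMatrix, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (between / within mean square).

    Conventions for degenerate features: a feature constant across all
    samples scores 0 (no between-class variance); zero within-class variance
    with nonzero between-class variance scores +inf (with a warning). Each
    class must have at least 2 samples.
    """
    X = values.values if isinstance(values, OmicsMatrix) else np.asarray(values, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class {small[0]!r} has fewer than 2 samples")

    n = X.shape[0]
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c, nc in zip(classes, counts):
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        ssb += nc * (mc - grand) ** 2
        ssw += ((Xc - mc) ** 2).sum(axis=0)
    msb = ssb / (len(classes) - 1)
    msw = ssw / (n - len(classes))

    F = np.zeros(X.shape[1])
    ok = msw > 0
    F[ok] = msb[ok] / msw[ok]
    degenerate = (~ok) & (msb > 0)
    F[degenerate] = np.inf
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} feature(s) have zero within-class variance; "
            "F reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    # msw == 0 and msb == 0 (fully constant) stays 0
    return F


def anova_filter(scores: np.ndarray, rule: str = "top",
                 threshold: float = 0.5, top_j: int | None = None) -> np.ndarray:
    """Keep-mask from ANOVA F-scores under one of three rules.

    rule='drop_zero'  — drop only features with F == 0;
    rule='threshold'  — keep features with F < ``threshold`` (printed rule);
    rule='top'        — keep the ``top_j`` highest-F features (recommended).
    """
    scores = np.asarray(scores, dtype=float)
    if rule == "drop_zero":
        mask = scores != 0
    elif rule == "threshold":
        mask = scores < threshold
    elif rule == "top":
        if top_j is None:
            raise ValueError("rule='top' requires top_j")
        j = min(int(top_j), scores.size)
        order = np.argsort(-scores, kind="stable")
        mask = np.zeros(scores.size, dtype=bool)
        mask[order[:j]] = True
    else:
        raise ValueError(f"unknown ANOVA filter rule {rule!r}")
    if not mask.any():
        raise ValueError(f"ANOVA filter rule {rule!r} keeps no features")
    return mask


# ---------------------------------------------------------------------------
# I/O


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # cells that failed coercion but are not recognized missing markers
    bad = out.isna() & df.notna()
    for col in bad.columns[bad.any()]:
        rows = bad.index[bad[col]]
        for r in rows:
            cell = str(df.loc[r, col]).strip()
            if cell not in MISSING_MARKERS:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {r!r}, column {col!r}"
                )
    return out


def read_omics_csv(path, omics_tag: str = "other", sep: str | None = None) -> OmicsMatrix:
    """Read a delimited omics matrix: first row feature ids, first column sample ids."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0, dtype=object,
                     keep_default_na=False)
    df = df.replace(sorted(MISSING_MARKERS), np.nan)
    df = _coerce_numeric(df, path)
    return OmicsMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index],
                       [str(f) for f in df.columns], omics_tag)


def read_labels(path, sample_ids: list[str] | None = None, sep: str | None = None
                ) -> tuple[np.ndarray, list[str]]:
    """Read a two-column sample id -> class file.

    Returns integer labels in [0, p) plus the ordered class names. If
    ``sample_ids`` is given, labels are reordered to match.
    """
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0, dtype=object)
    col = df.columns[0]
    if sample_ids is not None:
        missing = set(sample_ids) - set(map(str, df.index))
        if missing:
            raise ValueError(f"labels missing for samples: {sorted(missing)[:5]}")
        df = df.loc[[s for s in sample_ids]]
    raw = df[col].astype(str).to_numpy()
    names = sorted(set(raw))
    lut = {c: i for i, c in enumerate(names)}
    return np.array([lut[c] for c in raw], dtype=int), names


# ---------------------------------------------------------------------------
# transformer


class OmicsPreprocessor:
    """Fit the clean/variance/ANOVA filter cascade on training data, apply anywhere.

    scikit-learn transformer conventions: statistics are computed in ``fit``
    (training samples only) and ``transform`` only applies the stored masks,
    so held-out samples never leak into filter statistics.

    Parameters
    ----------
    zero_fraction_limit : max tolerated fraction of zero entries per feature.
    variance_threshold : variance floor (0.1 is typical for expression data,
        0.001 for methylation beta values, 0 disables).
    anova_rule : 'top', 'threshold', or 'drop_zero'.
    anova_top_j : number of features kept under the 'top' rule.
    anova_threshold : F cut-off under the 'threshold' rule.
    """

    def __init__(self, zero_fraction_limit: float = 0.10,
                 variance_threshold: float = 0.0,
                 anova_rule: str = "top", anova_top_j: int = 200,
                 anova_threshold: float = 0.5):
        self.zero_fraction_limit = zero_fraction_limit
        self.variance_threshold = variance_threshold
        self.anova_rule = anova_rule
        self.anova_top_j = anova_top_j
        self.anova_threshold = anova_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            "zero_fraction_limit": self.zero_fraction_limit,
            "variance_threshold": self.variance_threshold,
            "anova_rule": self.anova_rule,
            "anova_top_j": self.anova_top_j,
            "anova_threshold": self.anova_threshold,
        }

    def set_params(self, **params) -> "OmicsPreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: OmicsMatrix | np.ndarray, y: np.ndarray) -> "OmicsPreprocessor":
        m = X if isinstance(X, OmicsMatrix) else OmicsMatrix(
            np.asarray(X, float),
            [f"s{i}" for i in range(np.asarray(X).shape[0])],
            [f"f{j}" for j in range(np.asarray(X).shape[1])],
        )
        y = np.asarray(y)
        report = FilterReport(list(m.feature_ids))

        cleaned, rep_c = clean_matrix(m, self.zero_fraction_limit)
        report.zero_fraction = rep_c.zero_fraction
        mask_clean = rep_c.combined_mask()
        report.add_stage("clean", mask_clean)

        filtered, rep_v = variance_filter(cleaned, self.variance_threshold)
        var_full = np.full(m.n_features, np.nan)
        var_full[mask_clean] = rep_v.variance
        report.variance = var_full
        mask_var = mask_clean.copy()
        mask_var[mask_clean] = rep_v.combined_mask()
        report.add_stage("variance", mask_var)

        scores = anova_f_scores(filtered.values, y)
        f_full = np.full(m.n_features, np.nan)
        f_full[mask_var] = scores
        report.f_score = f_full
        keep_local = anova_filter(scores, self.anova_rule,
                                  threshold=self.anova_threshold,
                                  top_j=self.anova_top_j)
        mask_anova = mask_var.copy()
        mask_anova[mask_var] = keep_local
        report.add_stage("anova", mask_anova)

        self.n_features_in_ = m.n_features
        self.keep_mask_ = report.combined_mask()
        self.report_ = report
        return self

    def transform(self, X: OmicsMatrix | np.ndarray):
        if not hasattr(self, "keep_mask_"):
            raise RuntimeError("OmicsPreprocessor is not fitted")
        if isinstance(X, OmicsMatrix):
            if X.n_features != self.n_features_in_:
                raise ValueError("feature count differs from fit-time matrix")
            return X.select_features(self.keep_mask_)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit-time matrix")
        return X[:, self.keep_mask_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
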