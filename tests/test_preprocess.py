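"""Cleaning, variance, and ANOVA-F feature filters."""

import numpy as np
import pytest
from scipy import stats

from modilm.preprocess import (
    OmicsMatrix,
    OmicsPreprocessor,
    anova_f_scores,
    anova_filter,
    clean_matrix,
    read_omics_csv,
    variance_filter,
)


def make_matrix(X, tag="other"):
    X = np.asarray(X, dtype=float)
    return OmicsMatrix(X, [f"s{i}" for i in range(X.shape[0])],
                       [f"f{j}" for j in range(X.shape[1])], tag)


class TestCleanMatrix:
    def test_zero_heavy_column_dropped(self):
        X = np.ones((4, 3))
        X[:, 1] = [0, 0, 0, 1]  # zero fraction 0.75 > 0.10
        cleaned, report = clean_matrix(make_matrix(X), 0.10)
        assert cleaned.feature_ids == ["f0", "f2"]
        assert report.combined_mask().tolist() == [True, False, True]

    def test_clean_data_is_identity(self):
        X = np.arange(1, 13).reshape(4, 3).astype(float)
        cleaned, _ = clean_matrix(make_matrix(X), 0.10)
        np.testing.assert_array_equal(cleaned.values, X)

    def test_exactly_the_violating_columns_dropped(self):
        # 20x50 matrix: 7 columns get >10% zeros, 3 get NaN
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 50)) + 5
        zero_cols = [2, 9, 11, 20, 33, 41, 48]
        nan_cols = [5, 17, 44]
        for c in zero_cols:
            X[:3, c] = 0.0  # 15% zeros
        for c in nan_cols:
            X[4, c] = np.nan
        cleaned, _ = clean_matrix(make_matrix(X), 0.10)
        # independent enumeration of violating columns
        expected_drop = sorted(zero_cols + nan_cols)
        kept = [int(f[1:]) for f in cleaned.feature_ids]
        assert sorted(set(range(50)) - set(kept)) == expected_drop

    def test_all_dropped_is_an_error(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="empty matrix"):
            clean_matrix(make_matrix(X), 0.10)


class TestVarianceFilter:
    def test_constant_column_dropped(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        filtered, _ = variance_filter(make_matrix(X), 0.1)
        assert filtered.feature_ids == ["f1"]

    def test_zero_threshold_is_identity_for_varying_columns(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 4))
        filtered, _ = variance_filter(make_matrix(X), 0.0)
        np.testing.assert_array_equal(filtered.values, X)

    def test_low_variance_columns_dropped_per_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 200))
        low = rng.choice(200, 30, replace=False)
        X[:, low] *= np.sqrt(0.05) / X[:, low].std(axis=0, ddof=1)
        filtered, report = variance_filter(make_matrix(X), 0.1)
        # one-pass oracle over column variances
        keep_oracle = np.array([np.var(X[:, j], ddof=1) > 0.1 for j in range(200)])
        assert not keep_oracle[low].any()
        np.testing.assert_array_equal(report.combined_mask(), keep_oracle)


class TestAnovaF:
    def test_constant_feature_scores_zero(self):
        X = np.ones((10, 1))
        y = np.repeat([0, 1], 5)
        assert anova_f_scores(X, y)[0] == 0.0

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 3))
        X[y == 1, 0] += 10.0
        F = anova_f_scores(X, y)
        # from-definition oracle: SSB / SSW mean squares per feature
        for j in range(3):
            x = X[:, j]
            grand = x.mean()
            ssb = sum((x[y == c].mean() - grand) ** 2 * (y == c).sum() for c in (0, 1))
            ssw = sum(((x[y == c] - x[y == c].mean()) ** 2).sum() for c in (0, 1))
            expected = (ssb / 1) / (ssw / 38)
            assert F[j] == pytest.approx(expected, abs=1e-8)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 3, 30)
        y[:6] = [0, 0, 1, 1, 2, 2]  # ensure >=2 per class
        X = rng.standard_normal((30, 8))
        F = anova_f_scores(X, y)
        for j in range(8):
            groups = [X[y == c, j] for c in np.unique(y)]
            assert F[j] == pytest.approx(stats.f_oneway(*groups).statistic, abs=1e-8)

    def test_zero_within_class_variance_is_inf_with_warning(self):
        y = np.repeat([0, 1, 2], 4)
        X = y.astype(float)[:, None]
        with pytest.warns(RuntimeWarning, match="zero within-class variance"):
            F = anova_f_scores(X, y)
        assert np.isinf(F[0])

    def test_small_class_is_an_error(self):
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_f_scores(np.ones((4, 2)), y)


class TestAnovaFilterRules:
    def test_drop_zero_rule(self):
        mask = anova_filter(np.array([0.0, 0.3, 2.1]), rule="drop_zero")
        assert mask.tolist() == [False, True, True]

    def test_top_j_rule(self):
        mask = anova_filter(np.array([5.0, 1.0, 3.0]), rule="top", top_j=2)
        assert mask.tolist() == [True, False, True]

    def test_threshold_rule_keeps_small_f(self):
        mask = anova_filter(np.array([0.2, 0.6, 0.4]), rule="threshold", threshold=0.5)
        assert mask.tolist() == [True, False, True]

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="keeps no features"):
            anova_filter(np.array([0.0, 0.0]), rule="drop_zero")


class TestPreprocessorPipeline:
    def test_composed_mask_equals_sequential_filters(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 60)) + 3
        X[:10, 5] = 0.0
        X[:, 7] = 1.0
        y = np.repeat([0, 1], 20)
        X[y == 1, :10] += 2.0

        prep = OmicsPreprocessor(variance_threshold=0.1, anova_rule="top",
                                 anova_top_j=15).fit(X, y)
        # sequential application
        m1, _ = clean_matrix(make_matrix(X), 0.10)
        m2, _ = variance_filter(m1, 0.1)
        keep = anova_filter(anova_f_scores(m2.values, y), "top", top_j=15)
        sequential = [f for f, k in zip(m2.feature_ids, keep) if k]
        composed = [f"f{j}" for j in np.flatnonzero(prep.keep_mask_)]
        assert composed == sequential

    def test_transform_applies_stored_mask_without_recomputation(self):
        rng = np.random.default_rng(10)
        Xtr = rng.standard_normal((30, 20))
        y = np.repeat([0, 1], 15)
        Xtr[y == 1, :5] += 3.0
        prep = OmicsPreprocessor(anova_top_j=5).fit(Xtr, y)
        mask_before = prep.keep_mask_.copy()
        # held-out samples with a wildly different distribution
        Xte = rng.standard_normal((10, 20)) * 100
        out = prep.transform(Xte)
        assert out.shape == (10, 5)
        np.testing.assert_array_equal(prep.keep_mask_, mask_before)


class TestIO:
    def test_round_trip_and_missing_markers(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,f1,f2\ns1,1.5,NA\ns2,2.0,3.0\n")
        m = read_omics_csv(path, omics_tag="mRNA")
        assert m.omics_tag == "mRNA"
        assert np.isnan(m.values[0, 1])
        assert m.values[1, 1] == 3.0

    def test_unrecognized_token_is_a_parse_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,f1\ns1,oops\n")
        with pytest.raises(ValueError, match="oops"):
            read_omics_csv(path)
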