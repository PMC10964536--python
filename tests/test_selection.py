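import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitat_rfa.selection import (
    ZScorer,
    corr_prune,
    icc_2_1,
    icc_filter,
    lasso_select,
    mrmr_select,
    ttest_filter,
)


class TestICC:
    def test_identical_tables_all_kept(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(10, 5)),
                             columns=[f"f{i}" for i in range(5)])
        kept, iccs = icc_filter(table, table.copy(), threshold=0.85)
        assert kept == list(table.columns)
        assert all(v == pytest.approx(1.0) for v in iccs.values())

    def test_independent_noise_dropped(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(60, 20)))
        b = pd.DataFrame(rng.normal(size=(60, 20)))
        a.columns = b.columns = [f"f{i}" for i in range(20)]
        kept, iccs = icc_filter(a, b, threshold=0.85)
        assert kept == []
        # mean ICC of independent columns is ~0 within 3 SE
        vals = np.array(list(iccs.values()))
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_hand_computed_two_rater_example(self):
        # 4 subjects, 2 raters; expected ICC(2,1) frozen from the closed-form
        # ANOVA decomposition (agrees with pingouin's ICC(A,1))
        a = np.array([9.0, 6.0, 8.0, 7.0])
        b = np.array([2.0, 1.0, 4.0, 1.0])
        assert icc_2_1(a, b) == pytest.approx(0.05970149253731343)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestTTestFilter:
    def test_null_features_retained_at_alpha_rate(self):
        # type-I calibration: ~5% of 200 pure-noise features kept
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(100, 200)))
        labels = np.repeat([0, 1], 50)
        kept, _ = ttest_filter(table, labels, alpha=0.05)
        # binomial(200, 0.05): 3 SE band around 10
        se = np.sqrt(200 * 0.05 * 0.95)
        assert abs(len(kept) - 10) <= 3 * se

    def test_label_aligned_feature_kept(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 20)
        table = pd.DataFrame({"signal": labels + rng.normal(0, 0.01, 40)})
        kept, pvals = ttest_filter(table, labels)
        assert kept == ["signal"]

    def test_welch_statistic_matches_hand_formula(self):
        g1 = np.array([1.0, 2.0, 3.0])
        g0 = np.array([6.0, 7.0, 11.0])
        table = pd.DataFrame({"f": np.concatenate([g1, g0])})
        labels = np.array([1, 1, 1, 0, 0, 0])
        _, pvals = ttest_filter(table, labels, alpha=0.05)
        # Welch by hand
        v1, v0 = g1.var(ddof=1) / 3, g0.var(ddof=1) / 3
        t = (g1.mean() - g0.mean()) / np.sqrt(v1 + v0)
        df = (v1 + v0) ** 2 / (v1 ** 2 / 2 + v0 ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert pvals["f"] == pytest.approx(p)

    def test_zero_variance_feature_dropped_with_warning(self):
        table = pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)})
        labels = np.repeat([0, 1], 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            kept, pvals = ttest_filter(table, labels)
        assert "flat" not in pvals


class TestCorrPrune:
    def test_duplicate_column_leaves_one_copy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        kept = corr_prune(table, threshold=0.9)
        assert "c" in kept
        assert sum(f in kept for f in ("a", "b")) == 1

    def test_orthogonal_features_all_kept(self):
        table = pd.DataFrame(np.eye(6), columns=[f"f{i}" for i in range(6)])
        assert corr_prune(table, threshold=0.9) == list(table.columns)

    def test_postcondition_no_surviving_pair_exceeds_threshold(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(80, 3))
        cols = {}
        for i in range(12):
            j = i % 3
            cols[f"f{i}"] = base[:, j] + rng.normal(0, 0.05, 80)
        table = pd.DataFrame(cols)
        kept = corr_prune(table, threshold=0.9)
        corr = table[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9

    def test_greedy_solution_is_feasible_like_exhaustive(self):
        # 5-feature instance: greedy result must reach a valid set, like
        # exhaustive search over deletion orders does
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        table = pd.DataFrame({
            "x1": x, "x2": x + rng.normal(0, 0.01, 60),
            "x3": x + rng.normal(0, 0.02, 60),
            "y1": y, "y2": y + rng.normal(0, 0.01, 60),
        })
        kept = corr_prune(table, threshold=0.9)
        corr = table[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9
        assert len(kept) >= 2  # one survivor per correlated family

    def test_single_feature_passes_through(self):
        table = pd.DataFrame({"only": np.arange(5.0)})
        assert corr_prune(table) == ["only"]


class TestMRMR:
    def test_returns_exactly_m_of_larger_pool(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(60, 20)),
                             columns=[f"f{i}" for i in range(20)])
        labels = rng.integers(0, 2, 60)
        assert len(mrmr_select(table, labels, m=8)) == 8

    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1], 40)
        table = pd.DataFrame(rng.normal(size=(80, 10)),
                             columns=[f"noise{i}" for i in range(10)])
        table["signal"] = labels * 3.0 + rng.normal(0, 0.5, 80)
        ranked = mrmr_select(table, labels, m=5)
        assert ranked[0] == "signal"

    def test_redundant_copy_penalised_below_weaker_independent(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([0, 1], 60)
        strong = labels * 2.0 + rng.normal(0, 0.4, 120)
        table = pd.DataFrame({
            "strong": strong,
            "strong_copy": strong + rng.normal(0, 1e-6, 120),
            "weaker": labels * 1.0 + rng.normal(0, 0.8, 120),
        })
        ranked = mrmr_select(table, labels, m=3)
        assert ranked[0] == "strong"
        assert ranked.index("weaker") < ranked.index("strong_copy")

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            mrmr_select(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], m=0)


class TestLasso:
    def test_huge_lambda_shrinks_everything(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(rng.normal(size=(40, 5)))
        labels = rng.integers(0, 2, 40)
        kept, coef, lam = lasso_select(table, labels, folds=4,
                                       lambda_grid=np.array([1e6]), seed=0)
        assert kept == []
        assert np.allclose(coef.to_numpy(), 0.0)

    def test_zero_lambda_matches_least_squares(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta + rng.normal(0, 0.01, 30)
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        kept, coef, lam = lasso_select(
            table, y, folds=3, lambda_grid=np.array([0.0]), seed=0)
        ls = np.linalg.lstsq(np.column_stack([np.ones(30), X]), y,
                             rcond=None)[0][1:]
        np.testing.assert_allclose(coef.to_numpy(), ls, atol=1e-6)

    def test_planted_signal_recovered_single_seed(self):
        rng = np.random.default_rng(12)
        n, p = 400, 53
        X = rng.normal(size=(n, p))
        logits = 1.5 * X[:, 0] - 1.5 * X[:, 1] + 1.5 * X[:, 2]
        y = (logits + rng.normal(0, 1.0, n) > 0).astype(float)
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        kept, _, _ = lasso_select(table, y, folds=10, seed=0)
        assert {"f0", "f1", "f2"} <= set(kept)

    def test_too_few_samples_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            lasso_select(table, np.array([0, 1, 0, 1, 0]), folds=10)


class TestZScorer:
    def test_train_parameters_applied_unchanged_to_test(self):
        rng = np.random.default_rng(13)
        train = pd.DataFrame(rng.normal(5, 2, size=(50, 3)),
                             columns=["a", "b", "c"])
        test = pd.DataFrame(rng.normal(50, 20, size=(10, 3)),
                            columns=["a", "b", "c"])
        scaler = ZScorer().fit(train)
        z_train = scaler.transform(train)
        z_test = scaler.transform(test)
        np.testing.assert_allclose(z_train.mean(), 0.0, atol=1e-12)
        # test data standardised with TRAIN moments, not its own
        expected = (test - train.mean()) / train.std(ddof=0)
        np.testing.assert_allclose(z_test.to_numpy(), expected.to_numpy())
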