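import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from habitat_rfa.evaluation import (
    EvaluationReport,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    roc_auc,
    youden_threshold,
)


def _pair_count_auc(scores, labels):
    """Exhaustive concordant-pair oracle (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_four_point_hand_case(self):
        # pairs: 0.9>0.7, 0.9>0.2, 0.6<0.7, 0.6>0.2 -> 3 of 4 concordant
        scores = np.array([0.9, 0.6, 0.7, 0.2])
        labels = np.array([1, 1, 0, 0])
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        auc, ci = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert ci[1] <= 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc(np.ones(10), np.repeat([0, 1], 5))
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(10, 50)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(_pair_count_auc(scores, labels))
            assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


def _auc_rows(scores, labels):
    """Mann-Whitney AUC for each row of (B, n) score/label matrices."""
    from scipy import stats
    ranks = stats.rankdata(scores, axis=1)
    m = labels.sum(axis=1)
    n0 = labels.shape[1] - m
    pos_rank_sum = (ranks * labels).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (pos_rank_sum - m * (m + 1) / 2) / (m * n0)


def _bootstrap_delong_oracle(sa, sb, labels, n_boot=100_000, seed=0):
    """Paired bootstrap two-sided p for the AUC difference (vectorised)."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    labels = np.asarray(labels)
    idx = rng.integers(0, n, size=(n_boot, n))
    y = labels[idx]
    ok = (y.min(axis=1) == 0) & (y.max(axis=1) == 1)
    diffs = _auc_rows(sa[idx], y) - _auc_rows(sb[idx], y)
    diffs = diffs[ok & np.isfinite(diffs)]
    observed = (roc_auc_score(labels, sa) - roc_auc_score(labels, sb))
    centred = diffs - diffs.mean()
    return float(np.mean(np.abs(centred) >= abs(observed)))


class TestDeLong:
    def test_identical_models(self):
        scores = np.array([0.2, 0.8, 0.3, 0.9])
        labels = np.array([0, 1, 0, 1])
        z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_against_paired_bootstrap_oracle_small_n(self):
        rng = np.random.default_rng(1)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        sa = np.where(labels == 1, 0.6, 0.4) + rng.normal(0, 0.2, 12)
        sb = rng.uniform(0, 1, 12)
        _, p = delong_test(sa, sb, labels)
        p_boot = _bootstrap_delong_oracle(sa, sb, labels, n_boot=100_000)
        assert p == pytest.approx(p_boot, abs=0.1)

    def test_reversed_scores_significantly_different(self):
        rng = np.random.default_rng(2)
        n = 200
        labels = rng.integers(0, 2, n)
        scores = np.clip(labels * 0.6 + rng.normal(0.2, 0.15, n), 0, 1)
        z, p = delong_test(scores, 1 - scores, labels)
        assert p < 1e-6

    def test_null_p_values_roughly_uniform(self):
        # KS check at coarse tolerance over seeded paired-noise simulations
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(300):
            labels = np.repeat([0, 1], 20)
            sa = rng.normal(size=40)
            sb = rng.normal(size=40)
            pvals.append(delong_test(sa, sb, labels)[1])
        from scipy import stats
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestYouden:
    def test_perfect_separation(self):
        thr, metrics = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert metrics["youden_j"] == pytest.approx(1.0)
        assert 0.2 < thr < 0.8

    def test_all_equal_scores_no_discrimination(self):
        _, metrics = youden_threshold(np.ones(8), np.repeat([0, 1], 4))
        assert metrics["youden_j"] == pytest.approx(0.0)

    def test_matches_exhaustive_threshold_scan(self):
        scores = np.array([0.15, 0.35, 0.4, 0.55, 0.7, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        thr, metrics = youden_threshold(scores, labels)
        best = -np.inf
        for t in np.linspace(0, 1, 1001):
            pred = scores >= t
            sens = (pred & (labels == 1)).sum() / 3
            spec = (~pred & (labels == 0)).sum() / 3
            best = max(best, sens + spec - 1)
        assert metrics["youden_j"] == pytest.approx(best)
        assert metrics["youden_j"] == pytest.approx(
            metrics["sensitivity"] + metrics["specificity"] - 1)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_zero_statistic(self):
        # within each probability group the observed rate equals the prob
        probs = np.concatenate([np.full(10, 0.2), np.full(10, 0.8)])
        labels = np.concatenate([
            np.array([1, 1] + [0] * 8), np.array([1] * 8 + [0, 0])])
        stat, p = hosmer_lemeshow(probs, labels, groups=2)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_two_group_case(self):
        # group A: 5 lesions at p=0.4, 3 events; group B: 5 at p=0.6, 2 events
        probs = np.array([0.4] * 5 + [0.6] * 5)
        labels = np.array([1, 1, 1, 0, 0, 1, 1, 0, 0, 0])
        stat, p = hosmer_lemeshow(probs, labels, groups=2)
        expected = ((3 - 2.0) ** 2 / (2.0 * (1 - 0.4))
                    + (2 - 3.0) ** 2 / (3.0 * (1 - 0.6)))
        assert stat == pytest.approx(expected)

    def test_calibrated_probabilities_rarely_rejected(self):
        # well-calibrated = probabilities from a correctly specified fitted
        # logistic model, the situation the G-2 df reference distribution
        # describes
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=(2000, 1))
            true_p = 1 / (1 + np.exp(-(0.3 + 1.2 * x[:, 0])))
            labels = (rng.random(2000) < true_p).astype(int)
            fit = LogisticRegression(C=1e6).fit(x, labels)
            probs = fit.predict_proba(x)[:, 1]
            _, p = hosmer_lemeshow(probs, labels, groups=10)
            hits += p > 0.05
        assert hits >= 18  # >= 90% of 20 seeds

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.full(5, 0.5), np.zeros(5), groups=10)


class TestDecisionCurve:
    def test_treat_none_identically_zero(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(size=30)
        labels = rng.integers(0, 2, 30)
        dca = decision_curve(probs, labels)
        assert np.allclose(dca["treat_none"], 0.0)

    def test_treat_all_limit_is_prevalence(self):
        labels = np.repeat([1, 0], [3, 7])
        dca = decision_curve(np.full(10, 0.5), labels,
                             thresholds=np.array([0.001]))
        assert dca["treat_all"].iloc[0] == pytest.approx(0.3, abs=0.01)

    def test_twenty_lesion_closed_form_at_quarter_threshold(self):
        # TP=4, FP=6 at pt=0.25 -> NB = 4/20 - (6/20)/3
        probs = np.array([0.9] * 4 + [0.3] * 6 + [0.1] * 10)
        labels = np.array([1] * 4 + [0] * 6 + [0] * 8 + [1] * 2)
        dca = decision_curve(probs, labels, thresholds=np.array([0.25]))
        assert dca["net_benefit"].iloc[0] == pytest.approx(4 / 20 - (6 / 20) / 3)

    def test_model_curve_bounded_by_prevalence(self):
        rng = np.random.default_rng(6)
        probs = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        dca = decision_curve(probs, labels)
        assert (dca["net_benefit"] <= labels.mean() + 1e-12).all()

    def test_threshold_outside_open_interval_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=np.array([1.0]))


class TestReport:
    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 15)
        probs = np.clip(labels * 0.5 + rng.normal(0.3, 0.2, 30), 0.01, 0.99)
        rep = EvaluationReport()
        rep.add_signature("demo", probs, labels)
        rep.add_delong("demo", "flip", probs, 1 - probs, labels)
        path = tmp_path / "report.json"
        rep.to_json(path)
        back = EvaluationReport.from_json(path)
        assert back.signatures["demo"]["auc"] == pytest.approx(
            rep.signatures["demo"]["auc"])
        assert back.delong["demo_vs_flip"]["p"] == pytest.approx(
            rep.delong["demo_vs_flip"]["p"])
        table = rep.summary_table()
        assert set(table.columns) >= {"ACC", "AUC", "Sensitivity",
                                      "Specificity", "PPV", "NPV", "Youden"}
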