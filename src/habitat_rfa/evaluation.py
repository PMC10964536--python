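"""Model comparison statistics implemented from their defining formulas.

* AUC via the Mann-Whitney statistic (ties count 1/2) with a DeLong
  structural-components variance for the confidence interval;
* the paired two-sided DeLong test for comparing correlated AUCs;
* Youden-index threshold selection with the usual confusion metrics;
* the Hosmer-Lemeshow C-statistic on deciles of risk;
* decision-curve analysis net benefit with treat-all / treat-none
  references.

Labels are 0/1 with 1 = the event (non-complete response).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "roc_auc",
    "delong_test",
    "youden_threshold",
    "hosmer_lemeshow",
    "decision_curve",
    "EvaluationReport",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return y


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (positives) and V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def roc_auc(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong-variance normal-approximation CI, clipped to [0,1]."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc, v10, v01 = _structural_components(s, y)
    m, n = int(y.sum()), int((1 - y).sum())
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    return float(auc), ci


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired two-sided DeLong test for the AUC difference of two models.

    Returns (z, p); a zero-variance difference gives p = 1 by convention.
    """
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("paired scores must align with labels")
    auc_a, v10_a, v01_a = _structural_components(sa, y)
    auc_b, v10_b, v01_b = _structural_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 1e-15:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def youden_threshold(scores, labels) -> tuple[float, dict[str, float]]:
    """Probability cutoff maximising sensitivity + specificity.

    Candidate thresholds are the midpoints between sorted unique scores
    (plus one below the minimum and one above the maximum); ties in J go to
    the lower threshold. A case is called positive when score >= threshold.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    cands = np.concatenate([
        [uniq[0] - 1.0],
        (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.empty(0),
        [uniq[-1] + 1.0],
    ])
    m = int(y.sum())
    n = len(y) - m
    best_t, best_j, best_metrics = None, -np.inf, None
    for t in cands:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = m - tp
        tn = n - fp
        sens = tp / m
        spec = tn / n
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
            best_metrics = {
                "accuracy": (tp + tn) / len(y),
                "sensitivity": sens,
                "specificity": spec,
                "ppv": tp / (tp + fp) if tp + fp else 0.0,
                "npv": tn / (tn + fn) if tn + fn else 0.0,
                "youden_j": j,
            }
    return best_t, best_metrics


def hosmer_lemeshow(probs, labels, groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow C-statistic on deciles of risk.

    Lesions are grouped into ``groups`` equal-count bins of predicted
    probability (ties kept together); the statistic is
    sum over groups of (O - E)^2 / (E (1 - E/n_g)), referred to a
    chi-square with groups - 2 degrees of freedom. Degenerate groups
    (expected count 0 or n_g) are merged with a neighbour, with a warning
    and a df adjustment.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(p)
    if n < 2 * groups:
        raise ValueError(f"need n >= 2*groups, got n={n}, groups={groups}")
    try:
        bins = pd.qcut(p, groups, duplicates="drop")
    except ValueError:
        bins = pd.Series(np.zeros(n))
    df_tab = pd.DataFrame({"p": p, "y": y, "g": bins})
    grouped = [
        (sub["y"].sum(), sub["p"].sum(), len(sub))
        for _, sub in df_tab.groupby("g", observed=True)
    ]
    # merge groups whose expected counts are degenerate
    merged: list[list[float]] = []
    for obs, exp, ng in grouped:
        if merged and (merged[-1][1] <= 1e-12 or merged[-1][1] >= merged[-1][2] - 1e-12):
            warnings.warn("merging a degenerate Hosmer-Lemeshow group")
            merged[-1][0] += obs
            merged[-1][1] += exp
            merged[-1][2] += ng
        else:
            merged.append([obs, exp, ng])
    # trailing degenerate group merges backwards
    if len(merged) > 1 and (merged[-1][1] <= 1e-12 or merged[-1][1] >= merged[-1][2] - 1e-12):
        warnings.warn("merging a degenerate Hosmer-Lemeshow group")
        last = merged.pop()
        merged[-1][0] += last[0]
        merged[-1][1] += last[1]
        merged[-1][2] += last[2]
    stat = 0.0
    for obs, exp, ng in merged:
        denom = exp * (1.0 - exp / ng)
        if denom <= 1e-12:
            continue
        stat += (obs - exp) ** 2 / denom
    dof = max(len(merged) - 2, 1)
    pval = float(stats.chi2.sf(stat, dof))
    return float(stat), pval


def decision_curve(
    probs, labels, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt) over a threshold grid.

    Returns a table with the model curve plus treat-all and treat-none
    references. Default grid: 0.01 to 0.99 in steps of 0.01.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("threshold probabilities must lie in (0, 1)")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        pred = p >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        w = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * w,
            "treat_all": prevalence - (1 - prevalence) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Per-signature performance summary plus pairwise DeLong comparisons."""

    signatures: dict[str, dict] = field(default_factory=dict)
    delong: dict[str, dict] = field(default_factory=dict)

    def add_signature(self, name: str, probs, labels,
                      threshold: float | None = None,
                      dca_thresholds: np.ndarray | None = None) -> dict:
        """Evaluate one signature's predicted probabilities.

        ``threshold`` is the (training-derived) Youden cutoff; if None it is
        derived from the supplied scores.
        """
        probs = np.asarray(probs, dtype=float)
        y = _check_binary(labels)
        auc, ci = roc_auc(probs, y)
        if threshold is None:
            threshold, metrics = youden_threshold(probs, y)
        else:
            pred = probs >= threshold
            tp = int(np.sum(pred & (y == 1)))
            fp = int(np.sum(pred & (y == 0)))
            fn = int(y.sum()) - tp
            tn = int((1 - y).sum()) - fp
            sens = tp / max(tp + fn, 1)
            spec = tn / max(tn + fp, 1)
            metrics = {
                "accuracy": (tp + tn) / len(y),
                "sensitivity": sens,
                "specificity": spec,
                "ppv": tp / (tp + fp) if tp + fp else 0.0,
                "npv": tn / (tn + fn) if tn + fn else 0.0,
                "youden_j": sens + spec - 1.0,
            }
        hl_stat, hl_p = hosmer_lemeshow(probs, y, groups=min(10, len(y) // 2))
        dca = decision_curve(probs, y, dca_thresholds)
        entry = {
            "auc": auc,
            "auc_ci": ci,
            "threshold": float(threshold),
            **metrics,
            "hl_statistic": hl_stat,
            "hl_p": hl_p,
            "dca": dca.to_dict(orient="list"),
        }
        self.signatures[name] = entry
        return entry

    def add_delong(self, name_a: str, name_b: str, scores_a, scores_b, labels):
        z, p = delong_test(scores_a, scores_b, labels)
        self.delong[f"{name_a}_vs_{name_b}"] = {"z": z, "p": p}

    def summary_table(self) -> pd.DataFrame:
        """Table-style summary (ACC, AUC, CI, Sens, Spec, PPV, NPV, Youden)."""
        rows = []
        for name, e in self.signatures.items():
            rows.append({
                "signature": name,
                "ACC": e["accuracy"],
                "AUC": e["auc"],
                "CI_low": e["auc_ci"][0],
                "CI_high": e["auc_ci"][1],
                "Sensitivity": e["sensitivity"],
                "Specificity": e["specificity"],
                "PPV": e["ppv"],
                "NPV": e["npv"],
                "Youden": e["youden_j"],
            })
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"signatures": self.signatures, "delong": self.delong},
            indent=2, default=float,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "EvaluationReport":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        rep = cls()
        rep.signatures = data["signatures"]
        rep.delong = data["delong"]
        return rep
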