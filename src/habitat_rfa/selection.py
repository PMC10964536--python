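"""Feature-selection cascade: ICC robustness filter, Welch t-test screen,
greedy correlation pruning, mRMR ranking, and cross-validated LASSO.

The cascade runs on training lesions only; z-score parameters fitted on the
training table are applied unchanged to the test table. Each stage records
its inputs, outputs and per-feature statistics in a :class:`SelectionTrace`
so the pipeline is auditable and replayable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionTrace",
    "ZScorer",
    "icc_filter",
    "icc_2_1",
    "ttest_filter",
    "corr_prune",
    "mrmr_select",
    "lasso_select",
]


@dataclass
class SelectionTrace:
    """Audit record of a selection cascade."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, features_in, features_out, stats_: dict | None = None):
        self.stages.append({
            "stage": name,
            "n_in": len(features_in),
            "n_out": len(features_out),
            "features_in": list(features_in),
            "features_out": list(features_out),
            "stats": stats_ or {},
        })

    def to_dict(self) -> dict:
        return {"stages": self.stages}


class ZScorer:
    """Train-fitted standardisation applied unchanged to held-out data."""

    def __init__(self):
        self.mean_: pd.Series | None = None
        self.std_: pd.Series | None = None

    def fit(self, table: pd.DataFrame) -> "ZScorer":
        self.mean_ = table.mean()
        self.std_ = table.std(ddof=0).replace(0.0, 1.0)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("ZScorer not fitted")
        return (table[self.mean_.index] - self.mean_) / self.std_

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """Two-way random, absolute-agreement, single-measure ICC for 2 raters.

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    with n subjects and k = 2 measurements.
    """
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError(f"ICC needs >= 3 subjects, got {n}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-15:
        return 1.0 if abs(msr - mse) < 1e-15 else 0.0
    return float((msr - mse) / denom)


def icc_filter(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    threshold: float = 0.85,
) -> tuple[list[str], dict[str, float]]:
    """Keep features whose ICC(2,1) between two measurements >= threshold.

    ``table_a`` and ``table_b`` are aligned lesion x feature tables from two
    raters (or test-retest extractions). Returns the kept names and the
    per-feature ICC values.
    """
    if len(table_a) < 3:
        raise ValueError("ICC filtering needs at least 3 lesions")
    common = [c for c in table_a.columns if c in table_b.columns]
    kept, iccs = [], {}
    for name in common:
        a = table_a[name].to_numpy(float)
        b = table_b.loc[table_a.index, name].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            continue
        icc = icc_2_1(a[ok], b[ok])
        iccs[name] = icc
        if icc >= threshold:
            kept.append(name)
    return kept, iccs


# ---------------------------------------------------------------------------
# Welch t-test screen


def ttest_filter(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], dict[str, float]]:
    """Welch two-sample t-test per feature; keep p < alpha.

    Zero-variance features (in both groups) are dropped with a warning.
    """
    y = np.asarray(labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("both classes need at least 2 lesions")
    kept, pvals = [], {}
    for name in table.columns:
        v = table[name].to_numpy(float)
        g1, g0 = v[y], v[~y]
        if np.nanstd(g1) == 0 and np.nanstd(g0) == 0:
            warnings.warn(f"dropping zero-variance feature {name!r}")
            continue
        t, p = stats.ttest_ind(g1, g0, equal_var=False, nan_policy="omit")
        pvals[name] = float(p)
        if p < alpha:
            kept.append(name)
    return kept, pvals


# ---------------------------------------------------------------------------
# greedy correlation pruning


def corr_prune(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy recursive deletion of highly correlated features.

    Repeatedly deletes the feature with the most partners at |r| > threshold
    (ties: larger mean |r|, then lexicographic name) until no pair exceeds
    the threshold.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    corr = table.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        over = sub > threshold
        if not over.any():
            break
        idx_alive = np.flatnonzero(alive)
        counts = over.sum(axis=1)
        mean_r = sub.mean(axis=1)
        names = [cols[i] for i in idx_alive]
        # worst offender: most partners, then larger mean |r|, then name
        order = sorted(
            range(len(idx_alive)),
            key=lambda i: (-counts[i], -mean_r[i], names[i]),
        )
        alive[idx_alive[order[0]]] = False
    return [c for c, a in zip(cols, alive) if a]


# ---------------------------------------------------------------------------
# mRMR (MID criterion)


def _discretize_ef(x: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency discretisation into up to ``bins`` levels."""
    ranks = stats.rankdata(x, method="average")
    return np.minimum((ranks - 1) * bins // len(x), bins - 1).astype(np.int64)


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two discrete label arrays."""
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    na, nb = ja.max() + 1, jb.max() + 1
    joint = np.bincount(ja * nb + jb, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_select(
    table: pd.DataFrame, labels: np.ndarray, m: int = 8, bins: int = 4
) -> list[str]:
    """Greedy mRMR with the MID (difference) criterion.

    Relevance is the mutual information of each (equal-frequency, 4-bin
    discretised) feature with the label; redundancy is the mean pairwise MI
    with features already selected. Returns min(m, p) names in selection
    order.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    cols = list(table.columns)
    y = np.asarray(labels)
    disc = {c: _discretize_ef(table[c].to_numpy(float), bins) for c in cols}
    relevance = {c: _mutual_info(disc[c], y) for c in cols}
    selected: list[str] = []
    candidates = set(cols)
    red_cache: dict[tuple[str, str], float] = {}
    while candidates and len(selected) < m:
        best, best_score = None, -np.inf
        for c in sorted(candidates):
            if selected:
                red = np.mean([
                    red_cache.setdefault(
                        (c, s), _mutual_info(disc[c], disc[s])
                    )
                    for s in selected
                ])
            else:
                red = 0.0
            score = relevance[c] - red
            if score > best_score:
                best, best_score = c, score
        selected.append(best)
        candidates.discard(best)
    return selected


# ---------------------------------------------------------------------------
# LASSO with CV-MSE lambda selection


def _lambda_grid(X: np.ndarray, y: np.ndarray, n: int = 100) -> np.ndarray:
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n)


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[str], pd.Series, float]:
    """L1-penalised linear model on the 0/1 outcome with CV-MSE lambda.

    lambda* minimises the stratified ``folds``-fold cross-validated mean
    squared error over the grid (default: 100 log-spaced values from
    lambda_max down to lambda_max * 1e-4). Returns the features with
    nonzero coefficients at lambda*, the coefficients, and lambda*.
    """
    y = np.asarray(labels, dtype=np.float64)
    n = len(y)
    if n <= folds:
        raise ValueError(f"need n > folds, got n={n}, folds={folds}")
    cols = list(table.columns)
    X = table.to_numpy(float)
    if lambda_grid is None:
        lambda_grid = _lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    def _fit(Xtr, ytr, lam):
        if lam <= 0:
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(ytr)), Xtr]), ytr, rcond=None
            )
            return coef[0], coef[1:]
        model = Lasso(alpha=lam, max_iter=20000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        return model.intercept_, model.coef_

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    strat = y.astype(int)
    cv_mse = np.zeros(lambda_grid.size)
    for tr, va in skf.split(X, strat):
        for j, lam in enumerate(lambda_grid):
            b0, b = _fit(X[tr], y[tr], lam)
            pred = b0 + X[va] @ b
            cv_mse[j] += np.mean((y[va] - pred) ** 2)
    cv_mse /= folds
    best = int(np.argmin(cv_mse))
    lam_star = float(lambda_grid[best])
    b0, b = _fit(X, y, lam_star)
    coef = pd.Series(b, index=cols)
    kept = [c for c in cols if abs(coef[c]) > 1e-12]
    return kept, coef, lam_star
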