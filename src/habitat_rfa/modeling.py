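"""Clinical screening and radiomics signature models.

The clinical signature follows the classical two-step screen: one-variable
logistic regressions, then a joint logistic fit of the variables passing
p < 0.05, retaining those still significant. Radiomics signatures are
fitted with a small grid search over classifier hyperparameters, scored by
stratified five-fold cross-validated AUC, refit on the full training set,
and frozen together with the training-set Youden threshold before any test
evaluation.

Covariate encoding (documented because published tables rarely state it):
sex M=1/F=0; primary site ordinal rectum=1 .. caecum=4; lobe ordinal
RUL=1 .. LLL=5 (upper-to-lower); electrode straight=1/expandable=0; flags
0/1. The outcome is 1 = non-complete response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .evaluation import roc_auc, youden_threshold
from .synthcohort import ELECTRODES, LOBES, PRIMARY_SITES, ClinicalRecord

__all__ = [
    "encode_clinical",
    "ScreeningResult",
    "univariate_screen",
    "multivariate_screen",
    "SignatureModel",
    "fit_signature",
    "predict",
    "DEFAULT_FAMILIES",
]

_SITE_CODE = {s: i + 1 for i, s in enumerate(PRIMARY_SITES)}
_LOBE_CODE = {l: i + 1 for i, l in enumerate(LOBES)}


def encode_clinical(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Numeric design matrix for the clinical covariates."""
    rows = []
    for r in records:
        rows.append({
            "age": r.age,
            "sex": 1 if r.sex == "M" else 0,
            "cea": r.cea,
            "ca199": r.ca199,
            "lymphadenopathy": int(r.lymphadenopathy),
            "systemic_treatment": int(r.systemic_treatment),
            "primary_site": _SITE_CODE[r.primary_site],
            "nodule_size": r.nodule_size,
            "lobe": _LOBE_CODE[r.lobe],
            "near_vessels": int(r.near_vessels),
            "near_pleura": int(r.near_pleura),
            "electrode": 1 if r.electrode == "straight" else 0,
            "pneumothorax": int(r.pneumothorax),
            "iah": int(r.iah),
        })
    return pd.DataFrame(rows)


@dataclass
class ScreeningResult:
    """Uni/multivariate logistic screening output."""

    univariate: pd.DataFrame = field(default_factory=pd.DataFrame)
    multivariate: pd.DataFrame = field(default_factory=pd.DataFrame)
    candidates: list[str] = field(default_factory=list)  # univariate p < gate
    retained: list[str] = field(default_factory=list)    # multivariate p < gate
    warnings: list[str] = field(default_factory=list)


def _logit_fit(X: pd.DataFrame, y: np.ndarray, ridge: float = 0.0):
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ridge > 0:
            res = model.fit_regularized(
                alpha=ridge, L1_wt=0.0, disp=0, maxiter=200
            )
            # Wald covariance from the ridge-stabilised Hessian
            H = -model.hessian(res.params) + 2 * ridge * np.eye(len(res.params))
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.diag(cov))
            params = pd.Series(res.params, index=Xc.columns)
            bses = pd.Series(bse, index=Xc.columns)
            return params, bses, True
        res = model.fit(disp=0, maxiter=200)
    return res.params, res.bse, res.mle_retvals.get("converged", False)


def _wald_rows(params: pd.Series, bse: pd.Series) -> pd.DataFrame:
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "coef": params,
        "or": np.exp(params),
        "or_ci_low": np.exp(params - 1.959963984540054 * bse),
        "or_ci_high": np.exp(params + 1.959963984540054 * bse),
        "p": p,
    })
    return out.drop(index="const", errors="ignore")


def univariate_screen(
    records_or_table, labels, alpha: float = 0.05
) -> ScreeningResult:
    """One-variable logistic regression per covariate (Wald OR, CI, p).

    Constant covariates and completely separated fits are excluded with a
    warning.
    """
    table = (
        records_or_table
        if isinstance(records_or_table, pd.DataFrame)
        else encode_clinical(records_or_table)
    )
    y = np.asarray(labels).astype(int)
    result = ScreeningResult()
    rows = []
    for name in table.columns:
        x = table[[name]].astype(float)
        if x[name].nunique() < 2:
            result.warnings.append(f"constant covariate {name!r} excluded")
            continue
        try:
            params, bse, converged = _logit_fit(x, y)
        except Exception:
            result.warnings.append(f"covariate {name!r} excluded (fit failure)")
            continue
        if not converged or np.any(np.abs(params) > 50):
            result.warnings.append(
                f"covariate {name!r} excluded (separation or non-convergence)"
            )
            continue
        row = _wald_rows(params, bse).loc[name]
        rows.append(row.rename(name))
        if row["p"] < alpha:
            result.candidates.append(name)
    result.univariate = pd.DataFrame(rows)
    return result


def multivariate_screen(
    records_or_table, labels, candidates: list[str] | None = None,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Joint logistic fit of the univariate-significant covariates.

    Retains covariates with multivariate Wald p < alpha as the clinical
    signature inputs; collinear designs fall back to a ridge-stabilised
    fit with a warning.
    """
    table = (
        records_or_table
        if isinstance(records_or_table, pd.DataFrame)
        else encode_clinical(records_or_table)
    )
    y = np.asarray(labels).astype(int)
    result = univariate_screen(table, y, alpha=alpha)
    if candidates is None:
        candidates = result.candidates
    if not candidates:
        return result
    X = table[list(candidates)].astype(float)
    try:
        params, bse, converged = _logit_fit(X, y)
        if not converged or np.any(~np.isfinite(bse)) or np.any(bse > 1e3):
            raise np.linalg.LinAlgError("ill-conditioned logistic fit")
    except Exception:
        result.warnings.append("collinear candidates: ridge-stabilised fit used")
        params, bse, _ = _logit_fit(X, y, ridge=1.0)
    multi = _wald_rows(pd.Series(params), pd.Series(bse))
    result.multivariate = multi
    result.retained = [c for c in candidates if multi.loc[c, "p"] < alpha]
    return result


# ---------------------------------------------------------------------------
# signature classifiers

# paper-architecture defaults: winners per signature, overridable by config
DEFAULT_FAMILIES = {
    "Clinical": "xgboost",
    "Intra": "rf",
    "Peri5": "lightgbm",
    "Peri10": "lightgbm",
    "Habitat": "extratrees",
    "HabitatPeri5": "xgboost",
}

_DEFAULT_GRIDS = {
    "lr": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
    "svm": [{"C": 0.5}, {"C": 2.0}],
    "knn": [{"n_neighbors": 3}, {"n_neighbors": 5}],
    "rf": [{"max_depth": 3}, {"max_depth": None}],
    "extratrees": [{"max_depth": 3}, {"max_depth": None}],
    "xgboost": [{"max_depth": 2}, {"max_depth": 3}],
    "lightgbm": [{"num_leaves": 7}, {"num_leaves": 15}],
    "mlp": [{"alpha": 1e-3}, {"alpha": 1e-2}],
}


def _make_estimator(family: str, hp: dict, seed: int):
    if family == "lr":
        return LogisticRegression(max_iter=2000, **hp)
    if family == "svm":
        return SVC(probability=True, random_state=seed, **hp)
    if family == "knn":
        return KNeighborsClassifier(**hp)
    if family == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **hp)
    if family == "extratrees":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed, **hp)
    if family == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(
            n_estimators=80, learning_rate=0.1, random_state=seed,
            eval_metric="logloss", verbosity=0, n_jobs=1, **hp,
        )
    if family == "lightgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(
            n_estimators=80, learning_rate=0.1, random_state=seed,
            min_child_samples=5, verbose=-1, n_jobs=1, **hp,
        )
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=1500, random_state=seed, **hp
        )
    raise ValueError(f"unknown classifier family {family!r}")


class _PrevalenceModel:
    """Fallback constant model when a signature retains no features."""

    def __init__(self, prevalence: float):
        self.prevalence = float(prevalence)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.prevalence)
        return np.column_stack([1 - p, p])


@dataclass
class SignatureModel:
    """A fitted signature: features, classifier, frozen Youden threshold."""

    name: str
    feature_list: list[str]
    family: str
    hyperparameters: dict
    estimator: object
    threshold: float
    cv_auc: float
    train_probs: np.ndarray | None = None


def fit_signature(
    table: pd.DataFrame,
    labels,
    family: str,
    grid: list[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
    name: str = "signature",
) -> SignatureModel:
    """Grid search over hyperparameters by stratified CV AUC, then refit.

    The decision threshold (Youden index on the refit training
    probabilities) is frozen here, before any test data is seen.
    """
    y = np.asarray(labels).astype(int)
    feature_list = list(table.columns)
    if not feature_list:
        est = _PrevalenceModel(y.mean()).fit(None, y)
        probs = est.predict_proba(np.empty((len(y), 0)))[:, 1]
        return SignatureModel(name, [], family, {}, est, 0.5, 0.5, probs)
    X = table.to_numpy(float)
    if grid is None:
        grid = _DEFAULT_GRIDS[family]
    elif grid == "first":
        grid = _DEFAULT_GRIDS[family][:1]
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < folds:
        n_splits = max(2, min(folds, int(min(np.bincount(y)))))
    else:
        n_splits = folds
    best_hp, best_auc = grid[0], -np.inf
    if len(grid) > 1:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for hp in grid:
            aucs = []
            for tr, va in skf.split(X, y):
                if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                    continue
                est = _make_estimator(family, hp, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                p = est.predict_proba(X[va])[:, 1]
                aucs.append(roc_auc(p, y[va])[0])
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            if mean_auc > best_auc:
                best_hp, best_auc = hp, mean_auc
    est = _make_estimator(family, best_hp, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
        train_probs = est.predict_proba(X)[:, 1]
    if len(np.unique(y)) == 2:
        thr, _ = youden_threshold(train_probs, y)
    else:
        thr = 0.5
    return SignatureModel(
        name=name, feature_list=feature_list, family=family,
        hyperparameters=best_hp, estimator=est, threshold=float(thr),
        cv_auc=best_auc if np.isfinite(best_auc) else 0.5,
        train_probs=train_probs,
    )


def predict(model: SignatureModel, table: pd.DataFrame) -> np.ndarray:
    """Predicted event probabilities for new lesions."""
    missing = [f for f in model.feature_list if f not in table.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    if not model.feature_list:
        return model.estimator.predict_proba(np.empty((len(table), 0)))[:, 1]
    X = table[model.feature_list].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.estimator.predict_proba(X)[:, 1]
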