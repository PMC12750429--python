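"""Four-step construction of the walking-independence prediction model.

Given the 26-predictor feature table with the binary outcome (walking
dependent = positive class):

1. missing values are imputed with the overall (both groups pooled)
   median of each variable;
2. an L1-penalized (lasso) logistic regression screens the predictors:
   the penalty weight lambda is chosen by stratified 10-fold
   cross-validation minimizing mean held-out binomial deviance, the model
   is refit at that lambda on all data, and the predictors with nonzero
   coefficients are retained;
3. every unordered pair of retained predictors whose Pearson correlation
   is *not* significant at alpha .05 defines a candidate two-predictor
   logistic model;
4. candidates are fit by maximum likelihood and compared by the Akaike
   information criterion, AIC = -2 log L + 2 k; the minimum-AIC model is
   evaluated (confusion matrix at probability threshold 0.5, accuracy /
   sensitivity / specificity, ROC and AUC with a stratified-bootstrap
   95% CI).

Predictors are standardized to zero mean and unit SD before both the
penalized screen and the candidate fits, so coefficients and odds ratios
are on the standardized scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_COLUMNS, LABEL_COLUMN, POSITIVE_CLASS
from .stats import CorrelationScreen, correlation_screen

#: coefficient magnitude past which a standardized two-predictor logistic
#: fit is treated as (quasi-)separated
_SEPARATION_LIMIT = 15.0


def impute_overall_median(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Replace every missing value with its variable's pooled median.

    The median is taken over all patients (both outcome groups), matching
    the handling of the sporadic missing motor scores and activation
    features in the cohort this emulates.  A fully missing variable is an
    error.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in out.columns if out[c].dtype.kind in "fiu"]
    for c in columns:
        col = out[c].astype(float)
        if col.isna().all():
            raise ValueError(f"variable {c!r} has no observed values to impute from")
        if col.isna().any():
            out[c] = col.fillna(float(col.median()))
    return out


def outcome_vector(table: pd.DataFrame) -> np.ndarray:
    """Binary outcome: 1 for the walking-dependent (positive) class."""
    return (table[LABEL_COLUMN] == POSITIVE_CLASS).to_numpy(dtype=float)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise zero-mean unit-SD scaling; returns (Z, mean, sd)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# step 2: lasso screen


@dataclass
class LassoScreenResult:
    optimal_lambda: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray          # mean held-out binomial deviance per lambda
    coefficients: dict[str, float]   # standardized coefficients at the optimum
    nonzero: list[str]
    intercept: float
    n_folds: int


if tuple(int(x) for x in sklearn.__version__.split(".")[:2]) >= (1, 8):
    _L1_KW = {"l1_ratio": 1.0}
else:  # pragma: no cover - older scikit-learn spelling
    _L1_KW = {"penalty": "l1"}


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """L1-penalized logistic fit minimizing mean deviance + lam * ||w||_1."""
    n = len(y)
    C = 1e10 if lam <= 0 else 1.0 / (n * lam)
    clf = LogisticRegression(
        C=C, solver="liblinear", intercept_scaling=100.0,
        tol=1e-8, max_iter=10_000, **_L1_KW,
    )
    clf.fit(X, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_screen(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
) -> LassoScreenResult:
    """Cross-validated lasso screen over the candidate predictors.

    The lambda grid is ``n_lambdas`` log-spaced values from the smallest
    lambda that zeroes every coefficient down by ``lambda_decades``
    decades.  Folds are stratified by outcome and seeded.  Stage one
    picks the deviance-minimizing lambda (ties resolved toward the larger,
    more parsimonious lambda); stage two refits at that lambda on all
    data and reports the nonzero set.
    """
    predictors = list(predictors or FEATURE_COLUMNS)
    if table[predictors].isna().any().any():
        raise ValueError("screen requires a complete (imputed) table")
    y = outcome_vector(table)
    X_raw = table[predictors].to_numpy(dtype=float)
    X, _, _ = standardize(X_raw)
    n = len(y)
    # smallest lambda with all coefficients zero, for mean-deviance loss
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    grid = np.geomspace(lam_max, lam_max * 10.0**-lambda_decades, n_lambdas)
    n_min_class = int(min(y.sum(), n - y.sum()))
    k = min(n_folds, n_min_class)
    if k < 2:
        raise ValueError("need at least 2 members of each class for cross-validation")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    deviance = np.zeros(len(grid))
    for train, test in folds.split(X, y):
        for j, lam in enumerate(grid):
            coef, icpt = _l1_logistic(X[train], y[train], lam)
            eta = X[test] @ coef + icpt
            deviance[j] += _binomial_deviance(y[test], 1.0 / (1.0 + np.exp(-eta))) * len(test)
    deviance /= n
    best = int(np.argmin(deviance))  # argmin takes the first = largest lambda on ties
    lam_opt = float(grid[best])
    coef, icpt = _l1_logistic(X, y, lam_opt)
    coefficients = dict(zip(predictors, coef))
    nonzero = [p for p, c in coefficients.items() if c != 0.0]
    return LassoScreenResult(
        optimal_lambda=lam_opt, lambda_grid=grid, cv_deviance=deviance,
        coefficients=coefficients, nonzero=nonzero, intercept=icpt, n_folds=k,
    )


# ---------------------------------------------------------------------------
# step 3: candidate enumeration


def enumerate_candidates(
    nonzero: list[str],
    screen: CorrelationScreen,
) -> list[tuple[str, str]]:
    """All unordered predictor pairs whose correlation is not significant.

    Reproduces the rule that collinear (significantly correlated)
    predictors never enter the same two-variable model; with four screened
    variables of which exactly one pair is significantly correlated this
    yields five candidate models.
    """
    if len(nonzero) < 2:
        raise ValueError("need at least 2 screened predictors to form a pair")
    pairs = [
        (a, b) for a, b in itertools.combinations(sorted(nonzero), 2)
        if not screen.is_significant(a, b)
    ]
    if not pairs:
        raise ValueError("every screened predictor pair is significantly correlated")
    return pairs


# ---------------------------------------------------------------------------
# step 4: candidate fitting and AIC selection


@dataclass
class CandidateModelFit:
    pair: tuple[str, str]
    params: dict[str, float]          # intercept + standardized coefficients
    bse: dict[str, float]
    p_values: dict[str, float]
    aic: float
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    separated: bool
    n: int
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)  # (mean, sd)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.params["intercept"])
        for v in self.pair:
            mean, sd = self.scaling[v]
            eta = eta + self.params[v] * (table[v].to_numpy(dtype=float) - mean) / sd
        return eta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(table)))


def fit_candidate(table: pd.DataFrame, pair: tuple[str, str]) -> CandidateModelFit:
    """Maximum-likelihood logistic fit of the outcome on two predictors.

    Predictors are standardized; Wald standard errors, two-tailed
    p-values, AIC, and odds ratios with 95% Wald CIs are reported on the
    standardized scale.  (Quasi-)separated fits are flagged: coefficients
    diverge, and the AIC is reported from the deviance limit of the path,
    2 x number of parameters.
    """
    y = outcome_vector(table)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome has a single class")
    X_raw = table[list(pair)].to_numpy(dtype=float)
    Z, mean, sd = standardize(X_raw)
    exog = sm.add_constant(Z, has_constant="add")
    names = ["intercept", *pair]
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            pvals = np.asarray(res.pvalues, dtype=float)
            aic = float(res.aic)
            if not res.mle_retvals.get("converged", True) or np.max(np.abs(params)) > _SEPARATION_LIMIT:
                separated = True
        except Exception:
            separated = True
            params = np.full(3, np.nan)
            bse = np.full(3, np.inf)
            pvals = np.full(3, np.nan)
            aic = np.nan
    if separated:
        bse = np.full_like(bse, np.inf)
        if not np.all(np.isfinite(params)):
            # finite stand-in coefficients along the separation direction,
            # from a weakly ridge-stabilized fit, so predictions stay defined
            ridge = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
            ridge.fit(Z, y)
            params = np.concatenate([[ridge.intercept_[0]], ridge.coef_[0]])
        # AIC from the likelihood actually achieved at these coefficients:
        # under genuine separation the deviance is ~0 and this approaches the
        # path limit 2k; a fit that merely failed keeps its poor likelihood
        # and cannot win selection by failing
        p = np.clip(1.0 / (1.0 + np.exp(-(exog @ params))), 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        aic = 2.0 * exog.shape[1] - 2.0 * llf
    z975 = 1.959963984540054
    ors = {}
    ci = {}
    for i, name in enumerate(names):
        ors[name] = float(np.exp(params[i])) if np.isfinite(params[i]) else float("nan")
        if np.isfinite(params[i]) and np.isfinite(bse[i]):
            ci[name] = (float(np.exp(params[i] - z975 * bse[i])),
                        float(np.exp(params[i] + z975 * bse[i])))
        else:
            ci[name] = (0.0, float("inf"))
    return CandidateModelFit(
        pair=tuple(pair),
        params=dict(zip(names, map(float, params))),
        bse=dict(zip(names, map(float, bse))),
        p_values=dict(zip(names, map(float, pvals))),
        aic=aic,
        odds_ratios=ors,
        or_ci=ci,
        separated=separated,
        n=len(y),
        scaling={v: (float(m), float(s)) for v, m, s in zip(pair, mean, sd)},
    )


def null_model_aic(y: np.ndarray) -> float:
    """AIC of the intercept-only logistic model, in closed form.

    The MLE intercept reproduces the outcome prevalence p, so the log
    likelihood is n (p ln p + (1-p) ln(1-p)) and AIC = -2 logL + 2; a
    useful baseline against which candidate models are judged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = y.mean()
    if p in (0.0, 1.0):
        return 2.0
    return 2.0 - 2.0 * n * (p * np.log(p) + (1 - p) * np.log(1 - p))


def select_best(candidates: list[CandidateModelFit]) -> CandidateModelFit:
    """Minimum-AIC candidate; ties break toward the earlier pair in the
    deterministic (sorted-pair) candidate order."""
    if not candidates:
        raise ValueError("no candidate models")
    return min(candidates, key=lambda c: (c.aic,))


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    mode: str  # "in_sample" | "cross_validated"
    threshold: float


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion-matrix counts."""
    total = tp + fn + fp + tn
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def _bootstrap_auc_ci(
    y: np.ndarray, scores: np.ndarray, n_boot: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        fpr, tpr, _ = roc_curve(y[idx], scores[idx])
        aucs[i] = sk_auc(fpr, tpr)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def evaluate(
    model: CandidateModelFit,
    table: pd.DataFrame,
    threshold: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    mode: str = "in_sample",
    n_bootstrap: int = 2000,
) -> EvaluationReport:
    """Confusion matrix, accuracy/sensitivity/specificity, ROC and AUC.

    The walking-dependent class is positive.  ``mode='in_sample'`` scores
    the final fit on the full table (the default, matching a single
    confusion matrix over the whole cohort); ``mode='cross_validated'``
    refits the selected pair per stratified fold and scores held-out
    patients.  The AUC 95% CI is a stratified-bootstrap percentile
    interval over ``n_bootstrap`` resamples.
    """
    y = outcome_vector(table)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome has a single class")
    if mode == "in_sample":
        scores = model.predict_proba(table)
    elif mode == "cross_validated":
        k = min(cv_folds, int(min(y.sum(), len(y) - y.sum())))
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scores = np.empty(len(y))
        for train, test in folds.split(np.zeros(len(y)), y):
            fold_fit = fit_candidate(table.iloc[train], model.pair)
            scores[test] = fold_fit.predict_proba(table.iloc[test])
    else:
        raise ValueError("mode must be 'in_sample' or 'cross_validated'")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    metrics = confusion_metrics(tp, fn, fp, tn)
    fpr, tpr, _ = roc_curve(y, scores)
    auc_val = float(sk_auc(fpr, tpr))
    ci = _bootstrap_auc_ci(y, scores, n_bootstrap, seed)
    return EvaluationReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        accuracy=metrics["accuracy"], sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        roc_fpr=fpr, roc_tpr=tpr, auc=auc_val, auc_ci=ci,
        mode=mode, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# the full 4-step procedure


@dataclass
class PredictionReport:
    n_imputed: int
    screen: LassoScreenResult
    correlations: CorrelationScreen | None
    candidates: list[CandidateModelFit]
    best: CandidateModelFit | None
    evaluation: EvaluationReport | None
    error: str = ""


def build_prediction_model(
    table: pd.DataFrame,
    seed: int = 0,
    n_folds: int = 10,
    threshold: float = 0.5,
    evaluation_mode: str = "in_sample",
    n_bootstrap: int = 2000,
    predictors: list[str] | None = None,
) -> PredictionReport:
    """Run the complete 4-step procedure on a feature table."""
    predictors = list(predictors or FEATURE_COLUMNS)
    n_imputed = int(table[predictors].isna().to_numpy().sum())
    complete = impute_overall_median(table, predictors)
    screen = lasso_screen(complete, predictors, n_folds=n_folds, seed=seed)
    if len(screen.nonzero) < 2:
        return PredictionReport(n_imputed, screen, None, [], None, None,
                                error="fewer than 2 predictors survived the lasso screen")
    corr = correlation_screen(complete, screen.nonzero)
    try:
        pairs = enumerate_candidates(screen.nonzero, corr)
    except ValueError as exc:
        return PredictionReport(n_imputed, screen, corr, [], None, None, error=str(exc))
    candidates = [fit_candidate(complete, pair) for pair in pairs]
    best = select_best(candidates)
    report = evaluate(best, complete, threshold=threshold, seed=seed,
                      mode=evaluation_mode, n_bootstrap=n_bootstrap)
    return PredictionReport(n_imputed, screen, corr, candidates, best, report)
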