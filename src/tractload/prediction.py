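"""Stepwise multivariable regression of six-month motor outcome.

The final stage of the pipeline: a probability-of-F stepwise linear model
predicting the six-month upper-limb Fugl-Meyer score from the one-week
score, the dominant neuroimaging predictor (weighted premotor dorsal lesion
load), and dichotomized age — with the accompanying goodness-of-fit battery
(multicollinearity screen, casewise residual diagnostics, homoscedasticity
plot data, Kolmogorov-Smirnov normality test of standardized residuals,
Durbin-Watson statistic), a case-resampling bootstrap of the coefficients,
and adjusted-R^2 shrinkage as a cross-validation index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.stattools import durbin_watson

logger = logging.getLogger(__name__)


def dichotomize_age(age: float | np.ndarray, cut: float = 70.0) -> int | np.ndarray:
    """Indicator for age at or above ``cut`` years (default 70)."""
    arr = np.asarray(age, dtype=float)
    if (arr <= 0).any():
        raise ValueError("age must be positive")
    out = (arr >= cut).astype(int)
    return int(out) if np.isscalar(age) or arr.ndim == 0 else out


def adjusted_r2(r_squared: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1).

    The difference ``r_squared - adjusted_r2`` is the shrinkage estimate
    used as a cross-validation index.
    """
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - k - 1)


@dataclass
class StepwiseResult:
    """Trace and final state of a probability-of-F stepwise regression.

    ``steps`` has one row per model change: entered/removed predictor,
    predictors in the model, R, R^2, adjusted R^2, R^2-change with its
    partial-F p-value, and the standard error of the estimate (SEE, the
    residual standard deviation).
    """

    steps: pd.DataFrame
    selected: list[str]
    model: object | None  # statsmodels RegressionResults of the final fit
    coefficients: pd.DataFrame | None
    status: str = "ok"

    @property
    def r_squared(self) -> float:
        return float(self.model.rsquared) if self.model is not None else 0.0


def _fit(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    return sm.OLS(y, sm.add_constant(X[cols], has_constant="add")).fit()


def stepwise_regression(
    candidates: pd.DataFrame,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward-entry stepwise OLS with backward removal, on probability of F.

    At each iteration the not-yet-included candidate with the smallest
    entry p-value (the partial F-test of adding it) enters if that p-value
    is at most ``p_enter``; after every entry, any included predictor whose
    removal p-value is at least ``p_remove`` leaves.  Iteration stops when
    the model no longer changes.  Thresholds default to the conventional
    0.05 / 0.10 pair.
    """
    if p_enter >= p_remove:
        raise ValueError(
            f"p_enter ({p_enter}) must be < p_remove ({p_remove}) "
            "to preclude entry/removal cycling"
        )
    X = candidates.copy()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(X) != n:
        raise ValueError("candidates and outcome lengths differ")
    if n <= X.shape[1] + 1:
        raise ValueError(f"need n > #candidates + 1 (n={n})")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    if const:
        raise ValueError(f"constant candidates: {const}")

    included: list[str] = []
    step_rows = []
    prev_r2 = 0.0
    step_no = 0

    while True:
        changed = False
        remaining = [c for c in X.columns if c not in included]
        if remaining:
            pvals = {}
            for c in remaining:
                fit = _fit(X, y, included + [c])
                pvals[c] = float(fit.pvalues[c])
            best = min(pvals, key=pvals.get)
            if pvals[best] <= p_enter:
                included.append(best)
                changed = True
                step_no += 1
                fit = _fit(X, y, included)
                step_rows.append(_step_row(step_no, f"+{best}", included,
                                           fit, prev_r2, n))
                prev_r2 = float(fit.rsquared)
        # backward removal pass
        removed_any = True
        while removed_any and len(included) > 1:
            fit = _fit(X, y, included)
            pv = fit.pvalues.drop("const")
            worst = pv.idxmax()
            if float(pv[worst]) >= p_remove:
                included.remove(worst)
                changed = True
                step_no += 1
                fit = _fit(X, y, included)
                step_rows.append(_step_row(step_no, f"-{worst}", included,
                                           fit, prev_r2, n))
                prev_r2 = float(fit.rsquared)
            else:
                removed_any = False
        if not changed:
            break

    steps = pd.DataFrame(
        step_rows,
        columns=["step", "change", "predictors", "r", "r_squared",
                 "p_model", "adj_r_squared", "r2_change", "p_change", "see"],
    )
    if not included:
        return StepwiseResult(steps=steps, selected=[], model=None,
                              coefficients=None,
                              status="no candidate passed the entry criterion")
    final = _fit(X, y, included)
    coefs = pd.DataFrame({
        "coef": final.params,
        "se": final.bse,
        "t": final.tvalues,
        "p_value": final.pvalues,
    })
    return StepwiseResult(steps=steps, selected=included, model=final,
                          coefficients=coefs)


def _step_row(step_no, change, included, fit, prev_r2, n):
    r2 = float(fit.rsquared)
    k = len(included)
    delta = r2 - prev_r2
    # partial F for the one-variable change between consecutive models
    df_resid = n - k - 1
    if abs(delta) > 0 and r2 < 1.0 and df_resid > 0:
        F = abs(delta) / ((1.0 - r2) / df_resid)
        p_change = float(stats.f.sf(F, 1, df_resid))
    elif r2 >= 1.0:
        p_change = 0.0
    else:
        p_change = 1.0
    return {
        "step": step_no,
        "change": change,
        "predictors": ", ".join(included),
        "r": float(np.sqrt(r2)),
        "r_squared": r2,
        "p_model": float(fit.f_pvalue),
        "adj_r_squared": adjusted_r2(r2, n, k),
        "r2_change": delta,
        "p_change": p_change,
        "see": float(np.sqrt(fit.mse_resid)),
    }


def squared_semipartial(X: pd.DataFrame, pred: str, y: np.ndarray) -> float:
    """Unique contribution of ``pred``: R^2(full) - R^2(full without pred)."""
    if pred not in X.columns:
        raise KeyError(f"{pred!r} not among model predictors")
    y = np.asarray(y, dtype=float)
    full = _fit(X, y, list(X.columns))
    rest = [c for c in X.columns if c != pred]
    reduced_r2 = 0.0 if not rest else float(_fit(X, y, rest).rsquared)
    return float(full.rsquared) - reduced_r2


@dataclass
class DiagnosticsReport:
    """Goodness-of-fit battery for a fitted linear model."""

    predictor_correlations: pd.DataFrame
    max_abs_correlation: float
    multicollinearity_flagged: bool
    standardized_residuals: np.ndarray
    outlier_cases: list[int]
    #: plot-ready pairs: standardized predicted value vs studentized residual
    homoscedasticity_points: pd.DataFrame
    ks_statistic: float
    ks_p_value: float
    durbin_watson: float
    case_order: str
    shrinkage: float
    bootstrap_cis: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "max_abs_correlation": self.max_abs_correlation,
            "multicollinearity_flagged": self.multicollinearity_flagged,
            "outlier_cases": self.outlier_cases,
            "ks_statistic": self.ks_statistic,
            "ks_p_value": self.ks_p_value,
            "durbin_watson": self.durbin_watson,
            "case_order": self.case_order,
            "shrinkage": self.shrinkage,
        }
        if self.bootstrap_cis is not None:
            d["bootstrap_cis"] = self.bootstrap_cis.to_dict(orient="index")
        return d


def diagnostics(
    model,
    X: pd.DataFrame,
    y: np.ndarray,
    case_order: str = "file order",
    corr_threshold: float = 0.9,
    outlier_z: float = 3.0,
    normality_test: str = "ks",
) -> DiagnosticsReport:
    """Model-assumption checks for a fitted OLS model.

    * multicollinearity: pairwise Pearson correlations among predictors,
      flagged when any |r| reaches ``corr_threshold`` (0.9);
    * outliers: cases with |standardized residual| above ``outlier_z`` (3);
    * homoscedasticity: (standardized predicted, studentized residual)
      pairs for visual inspection — no numeric test is substituted;
    * normality: Kolmogorov-Smirnov test of the standardized residuals
      against a standard normal (``normality_test="lilliefors"`` applies the
      estimated-parameter correction instead);
    * independence: Durbin-Watson d over the supplied case order.  The data
      are cross-sectional, so d depends on that order; it is recorded in the
      report rather than hidden.
    """
    resid = np.asarray(model.resid, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    corr = X.corr(method="pearson")
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    max_abs = float(np.abs(off).max()) if X.shape[1] > 1 else 0.0

    std_resid = resid / np.sqrt(float(model.mse_resid))
    influence = model.get_influence()
    stud = influence.resid_studentized_internal
    fitted = np.asarray(model.fittedvalues, dtype=float)
    zpred = (fitted - fitted.mean()) / fitted.std(ddof=1)

    if normality_test == "lilliefors":
        ks_stat, ks_p = lilliefors(std_resid, dist="norm")
    else:
        ks_stat, ks_p = stats.kstest(std_resid, "norm")

    n = len(y)
    k = int(model.df_model)
    return DiagnosticsReport(
        predictor_correlations=corr,
        max_abs_correlation=max_abs,
        multicollinearity_flagged=max_abs >= corr_threshold,
        standardized_residuals=std_resid,
        outlier_cases=list(np.nonzero(np.abs(std_resid) > outlier_z)[0]),
        homoscedasticity_points=pd.DataFrame(
            {"standardized_predicted": zpred, "studentized_residual": stud}
        ),
        ks_statistic=float(ks_stat),
        ks_p_value=float(ks_p),
        durbin_watson=float(durbin_watson(resid)),
        case_order=case_order,
        shrinkage=float(model.rsquared) - adjusted_r2(float(model.rsquared), n, k),
    )


def bootstrap_coefficients(
    X: pd.DataFrame,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Percentile 95% confidence intervals by case-resampling bootstrap.

    Draws ``B`` resamples of the cases with replacement, refits the OLS
    model on each, and reports the 2.5th/97.5th percentiles per coefficient
    (intercept included).  Degenerate resamples (a constant predictor) are
    redrawn, at most ``max_redraws`` times each.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    A = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    n = len(y)
    point, *_ = np.linalg.lstsq(A, y, rcond=None)
    rng = np.random.default_rng(seed)
    draws = np.empty((B, A.shape[1]))
    for b in range(B):
        for _attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            Ab = A[idx]
            if (np.ptp(Ab[:, 1:], axis=0) == 0).any():
                continue
            draws[b], *_ = np.linalg.lstsq(Ab, y[idx], rcond=None)
            break
        else:
            logger.warning("degenerate resample persisted; reusing point "
                           "estimate for resample %d", b)
            draws[b] = point
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    return pd.DataFrame(
        {"coef": point, "ci_low": lo, "ci_high": hi},
        index=["const"] + cols,
    )
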