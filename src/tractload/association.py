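"""Cross-sectional association statistics.

Spearman rank correlations (with the Munro qualitative interpretation of
correlation magnitude) between clinical scores and per-tract weighted lesion
loads, and univariate ordinary-least-squares regressions of the six-month
outcome on each candidate predictor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Munro magnitude bands: upper edge (inclusive, on |rho| rounded to 2 dp) -> label.
DEFAULT_MUNRO_BANDS = (
    (0.25, "little/none"),
    (0.49, "low"),
    (0.69, "moderate"),
    (0.89, "high"),
    (1.00, "very high"),
)


class ConstantInputError(ValueError):
    """Raised when a correlation/regression input is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    munro_label: str


@dataclass(frozen=True)
class UnivariateResult:
    predictor: str
    outcome: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def munro_class(abs_rho: float, bands=DEFAULT_MUNRO_BANDS) -> str:
    """Qualitative label for a correlation magnitude.

    Bands (on |rho| at two-decimal precision): 0.00-0.25 little/none,
    0.26-0.49 low, 0.50-0.69 moderate, 0.70-0.89 high, 0.90-1.00 very high.
    """
    if not (0.0 <= abs_rho <= 1.0):
        raise ValueError(f"|rho| must be in [0, 1], got {abs_rho}")
    r = round(abs_rho, 2)
    for edge, label in bands:
        if r <= edge:
            return label
    return bands[-1][1]


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    *,
    x_name: str = "x",
    y_name: str = "y",
    method: str = "asymptotic",
    bands=DEFAULT_MUNRO_BANDS,
) -> CorrelationResult:
    """Spearman rank correlation with a 2-tailed p-value.

    Ranks use mid-rank ties.  ``method="asymptotic"`` (default) takes the
    p-value from the t-approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` on
    n-2 degrees of freedom, matching mainstream statistics packages at the
    cohort sizes this pipeline targets.  ``method="exact"`` runs a full
    permutation test and is only allowed for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("spearman(%s, %s): dropped %d incomplete cases",
                    x_name, y_name, dropped)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        rho = stats.spearmanr(x, y).statistic
        perm = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", alternative="two-sided",
        )
        p = float(perm.pvalue)
    else:
        res = stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, rho=float(rho), p_value=float(p),
        n=n, munro_label=munro_class(abs(float(rho)), bands),
    )


def correlation_matrix(
    table: pd.DataFrame,
    variables: list[str],
    bands=DEFAULT_MUNRO_BANDS,
) -> pd.DataFrame:
    """All pairwise Spearman correlations among ``variables``.

    Missing data are handled by pairwise-complete deletion.  Returns a tidy
    long-format DataFrame (one row per unordered pair plus the diagonal);
    use :func:`matrix_pivot` for the square rho/p layout.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    rows = []
    for v in variables:
        rows.append({"var1": v, "var2": v, "rho": 1.0, "p_value": 0.0,
                     "n": int(table[v].notna().sum()), "munro_label":
                     munro_class(1.0, bands)})
    for v1, v2 in itertools.combinations(variables, 2):
        try:
            res = spearman(table[v1].to_numpy(), table[v2].to_numpy(),
                           x_name=v1, y_name=v2, bands=bands)
            rho, p, n, label = res.rho, res.p_value, res.n, res.munro_label
        except ConstantInputError:
            logger.warning("correlation (%s, %s) undefined: constant vector; "
                           "cell recorded as NaN", v1, v2)
            rho = p = float("nan")
            n = int((table[v1].notna() & table[v2].notna()).sum())
            label = "undefined"
        rows.append({"var1": v1, "var2": v2, "rho": rho,
                     "p_value": p, "n": n, "munro_label": label})
        rows.append({"var1": v2, "var2": v1, "rho": rho,
                     "p_value": p, "n": n, "munro_label": label})
    return pd.DataFrame(rows)


def matrix_pivot(tidy: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Pivot the tidy correlation table to a square matrix of one field."""
    return tidy.pivot(index="var1", columns="var2", values=value)


def univariate_regression(
    x: np.ndarray,
    y: np.ndarray,
    *,
    predictor: str = "x",
    outcome: str = "y",
) -> UnivariateResult:
    """OLS regression of ``y`` on one predictor; R^2 and the slope's F-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete cases")
    if np.ptp(x) == 0:
        raise ConstantInputError(f"predictor {predictor!r} is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return UnivariateResult(
        predictor=predictor,
        outcome=outcome,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        n=int(x.size),
    )


def univariate_table(
    table: pd.DataFrame,
    predictors: list[str],
    outcome: str,
) -> pd.DataFrame:
    """Univariate regression of ``outcome`` on each predictor, one row each."""
    rows = []
    for p in predictors:
        res = univariate_regression(
            table[p].to_numpy(), table[outcome].to_numpy(),
            predictor=p, outcome=outcome,
        )
        rows.append({"predictor": p, "outcome": outcome, "slope": res.slope,
                     "intercept": res.intercept, "r_squared": res.r_squared,
                     "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)
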