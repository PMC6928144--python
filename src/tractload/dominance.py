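"""Dominance analysis: relative importance of correlated predictors.

When candidate predictors are strongly intercorrelated (as per-tract lesion
loads are, since the sub-pathways overlap anatomically), single-model
coefficients are a poor guide to relative importance.  Dominance analysis
instead compares predictors by their additional R^2 contribution across
*all* subset regressions:

* ``X`` **completely dominates** ``Y`` when X's additional contribution
  exceeds Y's for every subset of the remaining predictors;
* ``X`` **conditionally dominates** ``Y`` when X's average contribution
  exceeds Y's at every model size;
* ``X`` **generally dominates** ``Y`` when X's grand average (the general
  dominance weight) exceeds Y's.

Complete implies conditional implies general; ties at any level leave the
relation undetermined there (strict-inequality convention).  The general
dominance weights sum exactly to the full-model R^2.  Because the hierarchy
is estimated from one sample, a case-resampling bootstrap quantifies how
reproducible each pairwise designation is.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Negative floating-point slack treated as a zero additional contribution.
DELTA_CLIP = 1e-10

LEVELS = ("complete", "conditional", "general")


@dataclass
class SubsetR2Map:
    """R^2 of the OLS regression of the outcome on every predictor subset.

    ``r2`` maps each subset (frozenset of predictor names, including the
    empty set with R^2 = 0) to its coefficient of determination; a map over
    p predictors has exactly 2^p entries.  Subsets whose design matrix was
    rank deficient are listed in ``rank_deficient`` (their R^2 comes from
    the minimum-norm least-squares solution).
    """

    predictors: tuple[str, ...]
    r2: dict[frozenset, float]
    rank_deficient: list[frozenset] = field(default_factory=list)

    def __getitem__(self, subset) -> float:
        return self.r2[frozenset(subset)]


@dataclass
class DominanceStats:
    """Conditional averages, general weights, and pairwise designations."""

    predictors: tuple[str, ...]
    #: per predictor: mean additional R^2 at each subset size k = 0..p-1
    conditional: dict[str, np.ndarray]
    #: per predictor: mean of the conditional averages
    general: dict[str, float]
    #: (x, y) -> strongest level at which x dominates y, or None
    pairwise: dict[tuple[str, str], str | None]

    def designation(self, x: str, y: str, level: str) -> str:
        """Who dominates whom at ``level``: ``x``, ``y`` or ``"undetermined"``."""
        rank = LEVELS.index(level)
        for cand, other in ((x, y), (y, x)):
            lv = self.pairwise[(cand, other)]
            if lv is not None and LEVELS.index(lv) <= rank:
                return cand
        return "undetermined"


def _subset_r2(Xc: np.ndarray, yc: np.ndarray, sst: float,
               cols: tuple[int, ...]) -> tuple[float, bool]:
    """R^2 of centred OLS on the given columns; flags rank deficiency."""
    if not cols:
        return 0.0, False
    A = Xc[:, cols]
    coef, _, rank, _ = np.linalg.lstsq(A, yc, rcond=None)
    deficient = rank < len(cols)
    sse = float(((yc - A @ coef) ** 2).sum())
    return 1.0 - sse / sst, deficient


def all_subsets_r2(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                   names: list[str] | None = None) -> SubsetR2Map:
    """Exhaustively fit all 2^p subset regressions (with intercept).

    Centring both sides absorbs the intercept, so each subset needs one
    least-squares solve on the centred design.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if (np.ptp(X, axis=0) == 0).any():
        bad = [names[i] for i in range(p) if np.ptp(X[:, i]) == 0]
        raise ValueError(f"constant predictors: {bad}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sst = float((yc**2).sum())
    if sst == 0:
        raise ValueError("outcome is constant")
    r2: dict[frozenset, float] = {}
    deficient = []
    for k in range(p + 1):
        for cols in itertools.combinations(range(p), k):
            val, bad = _subset_r2(Xc, yc, sst, cols)
            key = frozenset(names[i] for i in cols)
            r2[key] = val
            if bad:
                deficient.append(key)
                logger.warning("rank-deficient subset %s: R^2 from "
                               "minimum-norm solution", sorted(key))
    return SubsetR2Map(predictors=tuple(names), r2=r2,
                       rank_deficient=deficient)


def additional_contribution(pred: str, subset, r2map: SubsetR2Map) -> float:
    """Additional R^2 of ``pred`` on top of ``subset``: R^2(S+pred) - R^2(S).

    Clipped to 0 when within the floating-point guard below zero.
    """
    S = frozenset(subset)
    if pred in S:
        raise ValueError(f"{pred!r} already in subset {sorted(S)}")
    delta = r2map.r2[S | {pred}] - r2map.r2[S]
    if delta < 0:
        if delta < -DELTA_CLIP:
            logger.warning("negative additional R^2 %.3e for %s | %s",
                           delta, pred, sorted(S))
        delta = 0.0
    return delta


def dominance_stats(r2map: SubsetR2Map) -> DominanceStats:
    """Conditional averages, general weights and pairwise dominance relations."""
    preds = r2map.predictors
    p = len(preds)
    others = {x: [q for q in preds if q != x] for x in preds}

    conditional = {}
    for x in preds:
        avgs = np.empty(p)
        for k in range(p):
            deltas = [
                additional_contribution(x, S, r2map)
                for S in map(frozenset, itertools.combinations(others[x], k))
            ]
            avgs[k] = float(np.mean(deltas))
        conditional[x] = avgs
    general = {x: float(conditional[x].mean()) for x in preds}

    pairwise: dict[tuple[str, str], str | None] = {}
    for x, y in itertools.permutations(preds, 2):
        rest = [q for q in preds if q not in (x, y)]
        complete = all(
            additional_contribution(x, S, r2map)
            > additional_contribution(y, S, r2map)
            for k in range(p - 1)
            for S in map(frozenset, itertools.combinations(rest, k))
        )
        cond = bool((conditional[x] > conditional[y]).all())
        gen = general[x] > general[y]
        if complete:
            level = "complete"
        elif cond:
            level = "conditional"
        elif gen:
            level = "general"
        else:
            level = None
        pairwise[(x, y)] = level
    return DominanceStats(predictors=preds, conditional=conditional,
                          general=general, pairwise=pairwise)


def conditional_table(stats: DominanceStats) -> pd.DataFrame:
    """Tidy table of mean additional R^2 per predictor and subset size."""
    rows = []
    for x in stats.predictors:
        for k, v in enumerate(stats.conditional[x]):
            rows.append({"predictor": x, "subset_size": k,
                         "mean_additional_r2": v})
    return pd.DataFrame(rows)


def bootstrap_reproducibility(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    names: list[str] | None = None,
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Reproducibility of every pairwise dominance designation under resampling.

    For each of ``B`` case resamples (drawn with replacement, seeded), the
    dominance analysis is recomputed; the reproducibility of a pairwise
    designation at a level is the fraction of resamples whose designation at
    that level matches the original sample's.  Resamples with a constant
    predictor are redrawn (at most ``max_redraws`` times, then counted as
    non-reproducing and logged).

    Returns a tidy DataFrame: ``predictor_1, predictor_2, level,
    original_designation, reproducibility``.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 (n={n}, p={p})")

    original = dominance_stats(all_subsets_r2(X, y, names=names))
    pairs = list(itertools.combinations(names, 2))
    matches = {(pr, lv): 0 for pr in pairs for lv in LEVELS}

    rng = np.random.default_rng(seed)
    for _ in range(B):
        boot = None
        for _attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
            if (np.ptp(Xb, axis=0) == 0).any() or np.ptp(yb) == 0:
                continue
            boot = dominance_stats(all_subsets_r2(Xb, yb, names=names))
            break
        if boot is None:
            logger.warning("degenerate resample persisted after %d redraws; "
                           "counted as non-reproducing", max_redraws)
            continue
        for x, yv in pairs:
            for lv in LEVELS:
                if boot.designation(x, yv, lv) == original.designation(x, yv, lv):
                    matches[((x, yv), lv)] += 1

    rows = []
    for (x, yv), lv in matches:
        rows.append({
            "predictor_1": x,
            "predictor_2": yv,
            "level": lv,
            "original_designation": original.designation(x, yv, lv),
            "reproducibility": matches[((x, yv), lv)] / B,
        })
    return pd.DataFrame(rows)


def reproducibility_range(report: pd.DataFrame, predictor: str,
                          level: str = "general") -> tuple[float, float]:
    """Min-max of a predictor's pairwise reproducibility values at one level."""
    sub = report[
        (report["level"] == level)
        & ((report["predictor_1"] == predictor)
           | (report["predictor_2"] == predictor))
    ]
    if sub.empty:
        raise KeyError(f"no pairs involving {predictor!r}")
    vals = sub["reproducibility"]
    return float(vals.min()), float(vals.max())
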