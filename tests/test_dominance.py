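"""Dominance analysis: subset-R2 oracle equivalence, hierarchy, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import tractload as tl
from tractload.dominance import (
    SubsetR2Map,
    additional_contribution,
    all_subsets_r2,
    bootstrap_reproducibility,
    conditional_table,
    dominance_stats,
    reproducibility_range,
)


def oracle_subset_r2(X, y, names):
    """Independent per-subset OLS refits via statsmodels."""
    out = {frozenset(): 0.0}
    df = pd.DataFrame(X, columns=names)
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            fit = sm.OLS(y, sm.add_constant(df[list(combo)])).fit()
            out[frozenset(combo)] = float(fit.rsquared)
    return out


def oracle_designations(r2, names):
    """Exhaustive recomputation of pairwise dominance from a raw subset map."""
    p = len(names)

    def delta(x, S):
        return max(r2[S | {x}] - r2[S], 0.0)

    cond = {}
    for x in names:
        rest = [q for q in names if q != x]
        cond[x] = [
            np.mean([delta(x, frozenset(S))
                     for S in itertools.combinations(rest, k)])
            for k in range(p)
        ]
    gen = {x: np.mean(cond[x]) for x in names}
    out = {}
    for x, y in itertools.permutations(names, 2):
        rest = [q for q in names if q not in (x, y)]
        complete = all(
            delta(x, frozenset(S)) > delta(y, frozenset(S))
            for k in range(p - 1)
            for S in itertools.combinations(rest, k)
        )
        conditional = all(a > b for a, b in zip(cond[x], cond[y]))
        general = gen[x] > gen[y]
        out[(x, y)] = (complete, conditional, general)
    return out


class TestAllSubsetsR2:
    def test_single_predictor_is_squared_pearson(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        m = all_subsets_r2(x[:, None], y, names=["p"])
        assert len(m.r2) == 2
        assert m[["p"]] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_exact_linear_outcome_full_r2_one(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + 3
        m = all_subsets_r2(X, y)
        assert m[m.predictors] == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_oracle(self, rng):
        for p in (2, 3, 4):
            X = rng.normal(size=(25, p))
            y = X @ rng.normal(size=p) + rng.normal(size=25)
            names = [f"x{i}" for i in range(p)]
            mine = all_subsets_r2(X, y, names=names)
            oracle = oracle_subset_r2(X, y, names)
            assert len(mine.r2) == 2**p
            for key, val in oracle.items():
                assert mine.r2[key] == pytest.approx(val, abs=1e-10)

    def test_monotone_under_inclusion(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        m = all_subsets_r2(X, y)
        for S, r in m.r2.items():
            for T, rt in m.r2.items():
                if S < T:
                    assert r <= rt + 1e-10

    def test_collinear_subset_flagged(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x])
        m = all_subsets_r2(X, rng.normal(size=30), names=["a", "b"])
        assert frozenset({"a", "b"}) in m.rank_deficient


class TestAdditionalContribution:
    def test_empty_subset_is_single_r2(self, rng):
        X = rng.normal(size=(30, 2))
        m = all_subsets_r2(X, rng.normal(size=30), names=["a", "b"])
        assert additional_contribution("a", [], m) == pytest.approx(m[["a"]])

    def test_duplicate_predictor_contributes_nothing(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, x.copy()])
        y = x + rng.normal(size=40)
        m = all_subsets_r2(X, y, names=["a", "twin"])
        assert additional_contribution("a", ["twin"], m) < 1e-9

    def test_pred_in_subset_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        m = all_subsets_r2(X, rng.normal(size=20), names=["a", "b"])
        with pytest.raises(ValueError):
            additional_contribution("a", ["a"], m)


class TestDominanceStats:
    def test_strong_signal_completely_dominates_noise(self, rng):
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        y = 2 * x1 + rng.normal(size=500)
        stats = dominance_stats(all_subsets_r2(
            np.column_stack([x1, x2]), y, names=["x1", "x2"]))
        assert stats.pairwise[("x1", "x2")] == "complete"
        assert stats.designation("x1", "x2", "complete") == "x1"

    def test_identical_predictors_undetermined(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        X = np.column_stack([x, x])
        stats = dominance_stats(all_subsets_r2(X, y, names=["a", "b"]))
        for level in ("complete", "conditional", "general"):
            assert stats.designation("a", "b", level) == "undetermined"

    def test_general_weights_sum_to_full_r2(self, rng):
        for p in (2, 3, 5):
            X = rng.normal(size=(40, p))
            y = X @ rng.normal(size=p) + rng.normal(size=40)
            m = all_subsets_r2(X, y)
            stats = dominance_stats(m)
            assert sum(stats.general.values()) == pytest.approx(
                m[m.predictors], abs=1e-9
            )

    def test_matches_exhaustive_designation_oracle(self, rng):
        for p in (3, 4, 5):
            X = rng.normal(size=(30, p))
            y = X @ rng.normal(size=p) + rng.normal(size=30)
            names = [f"x{i}" for i in range(p)]
            m = all_subsets_r2(X, y, names=names)
            stats = dominance_stats(m)
            oracle = oracle_designations(m.r2, names)
            for pair, (comp, cond, gen) in oracle.items():
                level = stats.pairwise[pair]
                assert (level == "complete") == comp
                assert (level in ("complete", "conditional")) == cond
                assert (level is not None) == gen

    def test_implication_hierarchy_on_random_instances(self, rng):
        for _ in range(10):
            p = int(rng.integers(2, 5))
            X = rng.normal(size=(25, p))
            y = X @ rng.normal(size=p) + rng.normal(size=25)
            m = all_subsets_r2(X, y)
            oracle = oracle_designations(m.r2, list(m.predictors))
            for comp, cond, gen in oracle.values():
                if comp:
                    assert cond, "complete must imply conditional"
                if cond:
                    assert gen, "conditional must imply general"

    def test_conditional_table_shape(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        table = conditional_table(dominance_stats(all_subsets_r2(X, y)))
        assert len(table) == 9  # 3 predictors x sizes 0..2


class TestBootstrapReproducibility:
    def test_same_seed_bit_reproducible(self, rng):
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + rng.normal(size=40)
        a = bootstrap_reproducibility(X, y, B=30, seed=7)
        b = bootstrap_reproducibility(X, y, B=30, seed=7)
        assert a.equals(b)

    def test_strong_signal_near_certain(self, rng):
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        y = x1.copy()
        rep = bootstrap_reproducibility(
            np.column_stack([x1, x2]), y, B=100, seed=1, names=["x1", "x2"])
        gen = rep[rep.level == "general"].iloc[0]
        assert gen.original_designation == "x1"
        assert gen.reproducibility >= 0.99

    def test_zero_resamples_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            bootstrap_reproducibility(X, rng.normal(size=20), B=0)

    def test_reproducibility_range_helper(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0] + rng.normal(size=40)
        rep = bootstrap_reproducibility(X, y, B=20, seed=2,
                                        names=["a", "b", "c"])
        lo, hi = reproducibility_range(rep, "a")
        assert 0.0 <= lo <= hi <= 1.0
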