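"""Stepwise model, diagnostics, coefficient bootstrap, adjusted R^2."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tractload.dominance import additional_contribution, all_subsets_r2
from tractload.prediction import (
    adjusted_r2,
    bootstrap_coefficients,
    diagnostics,
    dichotomize_age,
    squared_semipartial,
    stepwise_regression,
)


class TestDichotomizeAge:
    @pytest.mark.parametrize("age,expect", [(69, 0), (70, 1), (83, 1), (30, 0)])
    def test_cut_at_70_inclusive(self, age, expect):
        assert dichotomize_age(age) == expect

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_age(0)

    def test_vectorized(self):
        np.testing.assert_array_equal(
            dichotomize_age(np.array([65.0, 70.0, 95.0])), [0, 1, 1]
        )


class TestAdjustedR2:
    def test_reference_summary_value(self):
        # R^2 = 0.68 at n = 27, k = 1 shrinks to 0.67 at printed precision
        assert round(adjusted_r2(0.68, 27, 1), 2) == 0.67

    def test_perfect_fit_unshrunk(self):
        assert adjusted_r2(1.0, 27, 3) == pytest.approx(1.0)

    def test_zero_r2_goes_negative(self):
        assert adjusted_r2(0.0, 27, 3) == pytest.approx(1 - 26 / 23)

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 4, 3)


class TestStepwise:
    def test_single_true_predictor_enters_alone(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
        y = 3 * X.x1.to_numpy() + rng.normal(size=n)
        res = stepwise_regression(X, y)
        assert res.selected == ["x1"]
        assert len(res.steps) == 1

    def test_pure_noise_usually_empty(self):
        empty = 0
        for r in range(40):
            g = np.random.default_rng(100 + r)
            X = pd.DataFrame(g.normal(size=(200, 3)), columns=list("abc"))
            y = g.normal(size=200)
            if not stepwise_regression(X, y).selected:
                empty += 1
        # familywise entry chance ~ 1 - 0.95^3 ~ 14% per dataset
        assert empty >= 0.8 * 40 * 0.8  # comfortably most runs stay empty

    def test_r2_sequence_monotone_and_consistent(self, rng):
        n = 150
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = (2 * X.a + 1 * X.b + 0.5 * X.c).to_numpy() + rng.normal(size=n)
        res = stepwise_regression(X, y)
        steps = res.steps
        r2 = steps.r_squared.to_numpy()
        assert (np.diff(r2) >= -1e-12).all()
        np.testing.assert_allclose(steps.r.to_numpy(), np.sqrt(r2), atol=1e-12)
        np.testing.assert_allclose(
            steps.r2_change.to_numpy(), np.diff(np.concatenate([[0], r2])),
            atol=1e-12,
        )
        for _, row in steps.iterrows():
            k = len(row.predictors.split(", "))
            assert row.adj_r_squared == pytest.approx(
                adjusted_r2(row.r_squared, n, k), abs=1e-12
            )

    def test_bad_thresholds_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            stepwise_regression(X, rng.normal(size=20), p_enter=0.1, p_remove=0.05)

    def test_empty_model_status(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = rng.normal(size=100)
        res = stepwise_regression(X, y, p_enter=1e-9)
        assert res.selected == [] and res.model is None
        assert "entry" in res.status

    def test_removal_drops_superseded_composite(self, rng):
        # z ~ x1 + x2 enters first (best marginal fit) but becomes redundant
        # once its components are both in, so the backward pass removes it
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        z = x1 + x2 + 0.2 * rng.normal(size=n)
        y = 2 * x1 + x2 + 0.05 * rng.normal(size=n)
        res = stepwise_regression(pd.DataFrame({"z": z, "x1": x1, "x2": x2}), y)
        assert res.steps.change.iloc[0] == "+z"
        assert "-z" in set(res.steps.change)
        assert set(res.selected) == {"x1", "x2"}


class TestSemipartial:
    def test_orthogonal_identity(self, rng):
        # centred, exactly orthogonal predictors: R^2 decomposes additively,
        # so the semipartial of `a` equals its squared correlation with y
        a = rng.normal(size=60)
        a -= a.mean()
        b = rng.normal(size=60)
        b -= b.mean()
        b -= (a @ b) / (a @ a) * a
        X = pd.DataFrame({"a": a, "b": b})
        y = a + 0.5 * b + 0.1 * rng.normal(size=60)
        sp = squared_semipartial(X, "a", y)
        assert sp == pytest.approx(np.corrcoef(a, y)[0, 1] ** 2, abs=1e-10)

    def test_matches_dominance_additional_contribution(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = (X.a + X.b).to_numpy() + rng.normal(size=50)
        m = all_subsets_r2(X, y)
        for p in X.columns:
            rest = frozenset(set(X.columns) - {p})
            assert squared_semipartial(X, p, y) == pytest.approx(
                additional_contribution(p, rest, m), abs=1e-12
            )

    def test_absent_predictor_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(KeyError):
            squared_semipartial(X, "zzz", rng.normal(size=20))


class TestDiagnostics:
    def _fit(self, X, y):
        return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()

    def test_collinear_pair_flagged(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x + 1e-8 * rng.normal(size=50),
                          "c": rng.normal(size=50)})
        y = x + rng.normal(size=50)
        rep = diagnostics(self._fit(X, y), X, y)
        assert rep.multicollinearity_flagged
        assert rep.max_abs_correlation > 0.99

    def test_clean_fit_unflagged_no_outliers(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        y = (X.a - X.b).to_numpy() + rng.normal(size=80)
        rep = diagnostics(self._fit(X, y), X, y)
        assert not rep.multicollinearity_flagged
        assert rep.outlier_cases == []
        assert 0 <= rep.ks_statistic <= 1
        assert 0 <= rep.durbin_watson <= 4

    def test_alternating_residuals_push_dw_to_four(self):
        # y = alternating +1/-1 around a flat line: e_t - e_{t-1} = +-2
        n = 200
        x = np.linspace(0, 1, n)
        y = np.tile([1.0, -1.0], n // 2)
        X = pd.DataFrame({"x": x})
        rep = diagnostics(self._fit(X, y), X, y)
        assert rep.durbin_watson == pytest.approx(4.0, abs=0.1)

    def test_planted_outlier_detected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=60)})
        y = X.a.to_numpy() + 0.3 * rng.normal(size=60)
        y[10] += 12.0
        rep = diagnostics(self._fit(X, y), X, y)
        assert 10 in rep.outlier_cases

    def test_lilliefors_variant_runs(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        y = X.a.to_numpy() + rng.normal(size=50)
        rep = diagnostics(self._fit(X, y), X, y, normality_test="lilliefors")
        assert 0 <= rep.ks_p_value <= 1

    def test_shrinkage_is_r2_minus_adjusted(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X.a.to_numpy() + rng.normal(size=40)
        fit = self._fit(X, y)
        rep = diagnostics(fit, X, y)
        assert rep.shrinkage == pytest.approx(
            fit.rsquared - adjusted_r2(fit.rsquared, 40, 2), abs=1e-12
        )


class TestBootstrapCoefficients:
    def test_cis_contain_point_estimate(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        y = (2 * X.a - X.b).to_numpy() + rng.normal(size=80)
        cis = bootstrap_coefficients(X, y, B=200, seed=3)
        assert ((cis.ci_low <= cis.coef) & (cis.coef <= cis.ci_high)).all()

    def test_deterministic_data_zero_width(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = (3 * X.a + 1 - 2 * X.b).to_numpy()
        cis = bootstrap_coefficients(X, y, B=100, seed=1)
        np.testing.assert_allclose(cis.ci_low, cis.ci_high, atol=1e-8)
        np.testing.assert_allclose(cis.loc["a"].coef, 3.0, atol=1e-10)

    def test_seeded_reproducible(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X.a.to_numpy() + rng.normal(size=40)
        a = bootstrap_coefficients(X, y, B=150, seed=9)
        b = bootstrap_coefficients(X, y, B=150, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_b_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        with pytest.raises(ValueError):
            bootstrap_coefficients(X, rng.normal(size=30), B=10)
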