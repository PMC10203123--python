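import logging

import numpy as np
import pytest
import scipy.stats

from paleorange.stats import (
    aicc,
    ancova_fixed,
    compare_models,
    mixed_model,
    one_way_anova,
    ols_longevity,
    residual_diagnostics,
)

logging.disable(logging.WARNING)


# ----------------------------------------------------------------------
# closed-form two-variable least-squares oracle (explicit sum formulas),
# kept independent of the fitted implementation
def ols_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    b1 = sxy / sxx
    b0 = y.mean() - b1 * x.mean()
    resid = y - b0 - b1 * x
    sse = np.sum(resid**2)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1 - sse / sst if sst > 0 else 1.0
    se_b1 = np.sqrt(sse / (n - 2) / sxx)
    t = b1 / se_b1
    p = 2 * scipy.stats.t.sf(abs(t), n - 2)
    return b0, b1, r2, p


def anova_oracle(values, labels):
    """One-way ANOVA via the regression-on-dummy-variables formulation."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels))
    X = np.column_stack(
        [np.ones(len(values))] + [(labels == u).astype(float) for u in uniq[1:]]
    )
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    fitted = X @ beta
    sse = np.sum((values - fitted) ** 2)
    sst = np.sum((values - values.mean()) ** 2)
    df_b, df_w = len(uniq) - 1, len(values) - len(uniq)
    f = ((sst - sse) / df_b) / (sse / df_w)
    p = scipy.stats.f.sf(f, df_b, df_w)
    return f, p


# ----------------------------------------------------------------------
class TestOLS:
    def test_exact_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        m = ols_longevity(x, 2 * x + 1)
        assert m.r_squared == pytest.approx(1.0)
        assert m.coefficients["slope"] == pytest.approx(2.0)
        assert m.coefficients["intercept"] == pytest.approx(1.0)

    def test_zero_variance_predictor_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            ols_longevity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_closed_form_oracle(self):
        """100 random small instances agree with the explicit sum-formula
        least squares to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(0, rng.uniform(0.5, 3), n)
            y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * x
            m = ols_longevity(x, y)
            b0, b1, r2, p = ols_oracle(x, y)
            assert m.coefficients["intercept"] == pytest.approx(b0, abs=1e-10, rel=1e-10)
            assert m.coefficients["slope"] == pytest.approx(b1, abs=1e-10, rel=1e-10)
            assert m.r_squared == pytest.approx(r2, abs=1e-10)
            assert m.p_value == pytest.approx(p, abs=1e-10)

    def test_null_slope_r2_near_zero_large_n(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 5000)
        y = rng.normal(0, 1, 5000)
        m = ols_longevity(x, y)
        assert m.r_squared < 0.01

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        m = ols_longevity(x, rng.normal(0, 1, 50))
        assert abs(m.residuals.sum()) < 1e-8


class TestResidualDiagnostics:
    def test_perfect_fit_degenerate(self):
        x = np.linspace(0, 1, 20)
        d = residual_diagnostics(ols_longevity(x, 3 * x - 1))
        assert d["degenerate"]

    def test_quadratic_detected_by_runs_test(self):
        x = np.linspace(-3, 3, 60)
        d = residual_diagnostics(ols_longevity(x, x**2))
        assert d["runs_p"] < 0.001

    def test_well_specified_model_rarely_flagged(self):
        """Homoscedastic normal noise: each diagnostic stays non-significant
        at alpha=0.05 in >=90% of 200 seeds."""
        ok = {"shapiro_p": 0, "bp_p": 0, "runs_p": 0}
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 2, 80)
            y = 1 + 0.5 * x + rng.normal(0, 1, 80)
            d = residual_diagnostics(ols_longevity(x, y))
            for k in ok:
                ok[k] += d[k] > 0.05
        for k, n_ok in ok.items():
            assert n_ok / 200 >= 0.90, k


class TestAnova:
    def test_identical_groups_f_zero(self):
        v = [5.0, 5.0, 5.0, 5.0]
        a = one_way_anova(v, ["A", "A", "B", "B"])
        assert a.f_stat == pytest.approx(0.0)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 15)])
        labels = np.array(["A"] * 12 + ["B"] * 15)
        a = one_way_anova(v, labels)
        t, p = scipy.stats.ttest_ind(v[:12], v[12:], equal_var=True)
        assert a.f_stat == pytest.approx(t**2, rel=1e-10)
        assert a.p_value == pytest.approx(p, rel=1e-10)

    def test_matches_dummy_regression_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            k = rng.integers(2, 5)
            sizes = rng.integers(3, 12, size=k)
            v = np.concatenate([rng.normal(rng.uniform(-1, 1), 1, s) for s in sizes])
            labels = np.concatenate([[f"g{i}"] * s for i, s in enumerate(sizes)])
            a = one_way_anova(v, labels)
            f, p = anova_oracle(v, labels)
            assert a.f_stat == pytest.approx(f, rel=1e-10, abs=1e-10)
            assert a.p_value == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_small_group_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova([1.0, 2.0, 3.0], ["A", "A", "B"])


class TestAicc:
    def test_correction_term_hand_arithmetic(self):
        # k=2, n=10: 2*2*3/(10-3) = 12/7
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_limit_to_aic(self):
        ll, k = -123.4, 3
        aic = 2 * k - 2 * ll
        assert aicc(ll, k, 10**6) == pytest.approx(aic, abs=1e-4)

    def test_delta_invariant_to_loglik_shift(self):
        c = 57.3
        d1 = aicc(-100.0, 4, 50) - aicc(-98.0, 3, 50)
        d2 = aicc(-100.0 + c, 4, 50) - aicc(-98.0 + c, 3, 50)
        assert d1 == pytest.approx(d2)

    def test_small_n_is_error(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestModelComparison:
    def test_identical_models_delta_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        m = ols_longevity(x, y)
        cmp = compare_models(m, m)
        assert cmp["delta_aicc"] == 0.0

    def test_mismatched_n_is_error(self):
        rng = np.random.default_rng(2)
        m1 = ols_longevity(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        m2 = ols_longevity(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        with pytest.raises(ValueError):
            compare_models(m1, m2)

    def test_useless_parameter_penalized_by_about_one(self):
        """A redundant group factor on null data costs ~+1 AICc on average
        (the 2-point parameter penalty minus E[chi2_1] = 1 of loglik gain);
        the simpler model is preferred in the clear majority of seeds."""
        deltas = []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 2, 400)
            y = 1 + 0.5 * x + rng.normal(0, 1, 400)
            g = np.where(rng.random(400) < 0.5, "E", "C")
            cmp = compare_models(ancova_fixed(y, x, g), ols_longevity(x, y))
            deltas.append(cmp["delta_aicc"])
        mean_d = float(np.mean(deltas))
        assert 0.6 < mean_d < 1.5
        assert np.mean(np.array(deltas) > 0) > 0.75


class TestMixedModel:
    def test_zero_group_variance_matches_ols(self):
        """With no real between-group variance the random intercept collapses
        to ~0 and the fixed slope agrees with plain OLS to 1e-6."""
        rng = np.random.default_rng(42)
        x = rng.normal(0, 2, 200)
        y = 3 + 1.2 * x + rng.normal(0, 2, 200)
        g = np.where(rng.random(200) < 0.5, "E", "C")
        mm = mixed_model(y, x, g)
        ols = ols_longevity(x, y)
        assert mm.coefficients["group_var"] < 1e-4
        assert mm.coefficients["slope"] == pytest.approx(
            ols.coefficients["slope"], abs=1e-6
        )

    def test_group_offset_recovered(self):
        """A +3 my offset for one category: the fixed-factor variant's 95%
        CI covers the truth in >=90% of 200 seeds, and the mixed model's
        variance component moves off zero."""
        cover = 0
        var_pos = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 150
            x = rng.normal(0, 2, n)
            g = np.where(rng.random(n) < 0.5, "E", "C")
            y = 2 + 1.0 * x + 3.0 * (g == "E") + rng.normal(0, 2, n)
            a = ancova_fixed(y, x, g)
            key = next(k for k in a.coefficients if k.startswith("C(g)"))
            est, se = a.coefficients[key], a.std_errors[key]
            tcrit = scipy.stats.t.ppf(0.975, n - 3)
            cover += est - tcrit * se <= 3.0 <= est + tcrit * se
            if seed < 50:  # mixed fits are slower; a subsample suffices
                mm = mixed_model(y, x, g)
                var_pos += mm.coefficients["group_var"] > 0.1
        assert cover / 200 >= 0.90
        assert var_pos / 50 >= 0.90

    def test_single_category_is_error(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            mixed_model(
                rng.normal(0, 1, 20), rng.normal(0, 1, 20), ["E"] * 20
            )
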