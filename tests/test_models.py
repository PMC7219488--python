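"""Mixed and fixed-effects trend models: LMM, Tukey, IRLS, GLMM, LRT, curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from mrcprel.models import (
    ModelSpec,
    SeparationError,
    fit_glmm_logit_random_intercept,
    fit_lmm_random_intercept,
    fit_logistic_irls,
    irls_logistic,
    lrt,
    pairwise_tukey,
    probability_curve,
)


def glmm_oracle_data():
    """Random-intercept logistic data; the frozen reference values below were
    produced by an independent adaptive-quadrature fit (25 nodes) of the
    identical model in lme4 (glmer, nAGQ=25)."""
    rng = np.random.default_rng(2024)
    G, m = 20, 30
    u = rng.normal(0, 0.8, G)
    rows = []
    for g in range(G):
        x = rng.uniform(-1, 1, m)
        p = expit(-0.5 + 2.0 * x + u[g])
        y = (rng.random(m) < p).astype(int)
        for xi, yi in zip(x, y):
            rows.append((f"g{g:02d}", xi, yi))
    return pd.DataFrame(rows, columns=["g", "x", "y"])


class TestLMM:
    def test_zero_cluster_variance_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 40)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 40)
        # identical response pattern in every cluster -> no between-cluster var
        d = pd.DataFrame({
            "g": np.repeat([f"c{i}" for i in range(6)], 40),
            "x": np.tile(x, 6),
            "y": np.tile(y, 6),
        })
        fit = fit_lmm_random_intercept(d, ModelSpec("y", ["x"], cluster="g"))
        assert fit.boundary
        assert fit.random_intercept_sd < 1e-4
        ols = sm.OLS(d["y"], sm.add_constant(d["x"])).fit()
        assert fit.coef("Intercept") == pytest.approx(ols.params.iloc[0], abs=1e-3)
        assert fit.coef("x") == pytest.approx(ols.params.iloc[1], abs=1e-3)

    def test_balanced_one_way_closed_form_variance_components(self):
        rng = np.random.default_rng(5)
        g, m = 12, 8
        u = rng.normal(0, 2.0, g)
        rows = [(f"c{i}", 10 + u[i] + rng.normal(0, 1.0)) for i in range(g) for _ in range(m)]
        d = pd.DataFrame(rows, columns=["c", "y"])
        fit = fit_lmm_random_intercept(d, ModelSpec("y", ["1"], cluster="c"))
        x = d["y"].values.reshape(g, m)
        msb = m * ((x.mean(axis=1) - x.mean()) ** 2).sum() / (g - 1)
        msw = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (g * (m - 1))
        assert fit.random_intercept_sd == pytest.approx(np.sqrt((msb - msw) / m), rel=1e-3)

    def test_fixed_effect_recovery_in_clustered_design(self):
        # known condition effects with a small cluster sd: estimates land
        # within 3 SE of truth in nearly all replicates
        truth = {"a": 0.0, "b": 0.15, "c": -0.1}
        hits = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            rows = []
            for ci, cond in enumerate(truth):
                for d in range(10):
                    u = rng.normal(0, 0.1)
                    for _ in range(20):
                        rows.append((f"{cond}{d}", cond,
                                     0.4 + truth[cond] + u + rng.normal(0, 0.15)))
            df = pd.DataFrame(rows, columns=["dataset_id", "cond", "cs"])
            fit = fit_lmm_random_intercept(
                df, ModelSpec("cs", ["C(cond, Treatment('a'))"], cluster="dataset_id")
            )
            term = "C(cond, Treatment('a'))[T.b]"
            est = fit.coef(term)
            se = float(fit.params.loc[term, "se"])
            hits += abs(est - truth["b"]) <= 3 * se
        assert hits / reps >= 0.9


class TestTukey:
    def _fit(self, means, seed=0, m=30):
        rng = np.random.default_rng(seed)
        rows = []
        for cond, mu in means.items():
            for d in range(10):
                u = rng.normal(0, 0.05)
                for _ in range(m):
                    rows.append((f"{cond}{d}", cond, mu + u + rng.normal(0, 0.2)))
        df = pd.DataFrame(rows, columns=["dataset_id", "cond", "y"])
        spec = ModelSpec("y", ["C(cond)"], cluster="dataset_id")
        return fit_lmm_random_intercept(df, spec)

    def test_two_levels_reduces_to_plain_t_test(self):
        fit = self._fit({"a": 0.3, "b": 0.5})
        (c,) = pairwise_tukey(fit, "cond")
        p_t = 2 * stats.t.sf(abs(c.t_stat), c.df)
        assert c.adjusted_p == pytest.approx(p_t, rel=1e-6)

    def test_three_groups_match_studentized_range_oracle(self):
        fit = self._fit({"a": 0.2, "b": 0.45, "c": 0.5})
        for c in pairwise_tukey(fit, "cond"):
            q = abs(c.t_stat) * np.sqrt(2.0)
            expected = stats.studentized_range.sf(q, 3, c.df)
            assert c.adjusted_p == pytest.approx(expected, rel=1e-9)

    def test_identical_means_not_significant(self):
        fit = self._fit({"a": 0.4, "b": 0.4, "c": 0.4}, seed=4)
        assert all(c.adjusted_p > 0.2 for c in pairwise_tukey(fit, "cond"))

    def test_absent_factor_raises(self):
        fit = self._fit({"a": 0.3, "b": 0.5})
        with pytest.raises(ValueError, match="'group'"):
            pairwise_tukey(fit, "group")


class TestIRLS:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
        fit = irls_logistic(np.ones((10, 1)), y, names=["Intercept"])
        assert fit.coef("Intercept") == pytest.approx(logit(0.3), rel=1e-8)

    def test_two_by_two_table_log_odds_ratio(self):
        # cells: x=0 -> 20/100 events, x=1 -> 50/100 events; slope = log 4
        y = np.concatenate([np.ones(20), np.zeros(80), np.ones(50), np.zeros(50)])
        x = np.concatenate([np.zeros(100), np.ones(100)])
        fit = irls_logistic(np.column_stack([np.ones(200), x]), y, names=["b0", "x"])
        assert fit.coef("x") == pytest.approx(np.log(4.0), rel=1e-8)
        assert fit.coef("b0") == pytest.approx(logit(0.2), rel=1e-8)

    def test_all_ones_response_is_separation(self):
        with pytest.raises(SeparationError):
            irls_logistic(np.ones((20, 1)), np.ones(20))

    def test_formula_interface_matches_matrix_interface(self, rng):
        x = rng.uniform(-1, 1, 150)
        y = (rng.random(150) < expit(0.5 + 1.5 * x)).astype(int)
        df = pd.DataFrame({"x": x, "y": y})
        a = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        b = irls_logistic(np.column_stack([np.ones(150), x]), y)
        assert a.coef("x") == pytest.approx(b.params["estimate"].iloc[1], rel=1e-10)


class TestGLMM:
    def test_matches_frozen_lme4_reference(self):
        df = glmm_oracle_data()
        fit = fit_glmm_logit_random_intercept(
            df, ModelSpec("y", ["x"], cluster="g", family="binomial"), quad_points=25
        )
        assert fit.coef("Intercept") == pytest.approx(-0.3707075, abs=2e-4)
        assert fit.coef("x") == pytest.approx(1.9183473, abs=2e-4)
        assert float(fit.params.loc["Intercept", "se"]) == pytest.approx(0.2411162, abs=2e-3)
        assert float(fit.params.loc["x", "se"]) == pytest.approx(0.1962011, abs=2e-3)
        assert fit.random_intercept_sd == pytest.approx(0.9795418, abs=5e-4)
        assert fit.loglike == pytest.approx(-331.109, abs=5e-3)

    def test_no_group_variance_collapses_to_irls(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 40)
        y = (rng.random(40) < expit(0.3 + 1.2 * x)).astype(int)
        df = pd.DataFrame({
            "g": np.repeat(np.arange(8), 40), "x": np.tile(x, 8), "y": np.tile(y, 8)
        })
        glm = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        glmm = fit_glmm_logit_random_intercept(
            df, ModelSpec("y", ["x"], cluster="g", family="binomial")
        )
        assert glmm.boundary
        diff = np.abs(glm.params["estimate"].values - glmm.params["estimate"].values)
        assert diff.max() < 1e-3

    def test_quadrature_converged_at_default_node_count(self):
        df = glmm_oracle_data()
        spec = ModelSpec("y", ["x"], cluster="g", family="binomial")
        f25 = fit_glmm_logit_random_intercept(df, spec, quad_points=25)
        f50 = fit_glmm_logit_random_intercept(df, spec, quad_points=50)
        assert abs(f25.loglike - f50.loglike) < 1e-4

    def test_invalid_quad_points(self):
        df = glmm_oracle_data()
        with pytest.raises(ValueError, match="quad_points"):
            fit_glmm_logit_random_intercept(
                df, ModelSpec("y", ["x"], cluster="g", family="binomial"), quad_points=0
            )


class TestLRT:
    def test_identical_fits_give_zero(self):
        df = glmm_oracle_data()
        fit = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        res = lrt(fit, fit)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_tiny_negative_chi2_clamped(self):
        df = glmm_oracle_data()
        full = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        reduced = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        reduced.loglike = full.loglike + 1e-9  # numerically above the full fit
        reduced.n_params = full.n_params - 1
        res = lrt(full, reduced)
        assert res.chi2 == 0.0
        assert res.clamped

    def test_grossly_negative_chi2_raises(self):
        df = glmm_oracle_data()
        full = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        reduced = fit_logistic_irls(df, ModelSpec("y", ["x"], family="binomial"))
        reduced.loglike = full.loglike + 10.0
        reduced.n_params = full.n_params - 1
        with pytest.raises(ValueError, match="not converged"):
            lrt(full, reduced)


class TestProbabilityCurve:
    def _fit(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 400)
        y = (rng.random(400) < expit(-1.0 + 3.0 * x)).astype(int)
        return fit_logistic_irls(
            pd.DataFrame({"x": x, "y": y}), ModelSpec("y", ["x"], family="binomial")
        )

    def test_zero_linear_predictor_gives_half(self):
        fit = self._fit()
        x_half = -fit.coef("Intercept") / fit.coef("x")
        cur = probability_curve(fit, "x", [x_half])
        assert cur["probability"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_monotone_curve_for_positive_slope(self):
        fit = self._fit()
        cur = probability_curve(fit, "x", np.linspace(0, 1, 15))
        assert (np.diff(cur["probability"]) > 0).all()

    def test_ci_equals_transformed_wald_limits(self):
        fit = self._fit()
        grid = [0.2, 0.7]
        cur = probability_curve(fit, "x", grid)
        beta = fit.params["estimate"].values
        for i, g in enumerate(grid):
            xrow = np.array([1.0, g])
            eta = xrow @ beta
            se = np.sqrt(xrow @ fit.cov @ xrow)
            assert cur["ci_low"].iloc[i] == pytest.approx(expit(eta - 1.959963984540054 * se), rel=1e-9)
            assert cur["ci_high"].iloc[i] == pytest.approx(expit(eta + 1.959963984540054 * se), rel=1e-9)

    def test_extrapolation_flagged(self):
        fit = self._fit()
        cur = probability_curve(fit, "x", [-0.5, 0.5, 1.5])
        assert cur["extrapolated"].tolist() == [True, False, True]
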