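"""ZIP mixed model: pmf, marginal likelihood, fitting, LRT, predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_zip_glmm_data
from strokeconn.glmm import (
    ModelSpec,
    build_design,
    fit_zip_glmm,
    likelihood_ratio_test,
    marginal_loglik,
    predict_marginal_mean,
    zip_logpmf,
)


class TestZipLogpmf:
    def test_reduces_to_poisson_at_pi_zero(self):
        y = np.arange(6)
        assert np.allclose(
            zip_logpmf(y, 2.5, 0.0), stats.poisson.logpmf(y, 2.5), atol=1e-12
        )

    def test_zero_mass_formula(self):
        assert zip_logpmf(0, 1.0, 0.5) == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1)))

    def test_normalizes(self):
        y = np.arange(201)
        total = np.exp(zip_logpmf(y, 3.0, 0.3)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            zip_logpmf(1, -1.0, 0.2)
        with pytest.raises(ValueError):
            zip_logpmf(1, 1.0, 1.0)


class TestMarginalLoglik:
    spec = ModelSpec(response="count", fixed_terms=("x",))

    def test_sigma_zero_collapses_to_sum_of_logpmf(self):
        data = pd.DataFrame(
            {"subject": ["a", "a", "b"], "x": [0.0, 1.0, -1.0], "count": [2, 0, 1]}
        )
        beta = np.array([0.4, 0.2])
        L = marginal_loglik(self.spec, {"beta": beta, "sigma_u": 0.0, "pi": 0.1}, data)
        lam = np.exp(0.4 + 0.2 * data["x"].to_numpy())
        assert L == pytest.approx(zip_logpmf(data["count"], lam, 0.1).sum(), abs=1e-10)

    def test_matches_brute_force_integral(self):
        data = pd.DataFrame({"subject": ["a"], "x": [0.5], "count": [3]})
        params = {"beta": np.array([0.3, 0.2]), "sigma_u": 0.45, "pi": 0.15}
        L = marginal_loglik(self.spec, params, data)
        v = np.linspace(-9, 9, 10**6)
        lam = np.exp(0.3 + 0.2 * 0.5 + 0.45 * v)
        integrand = stats.norm.pdf(v) * np.exp(zip_logpmf(3, lam, 0.15))
        L_brute = np.log(np.trapezoid(integrand, v))
        assert L == pytest.approx(L_brute, abs=1e-6)

    def test_matches_poisson_glm_loglik_in_limit(self):
        """pi=0, sigma=0 equals an independent Poisson GLM log-likelihood."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.normal(size=150)
        y = rng.poisson(np.exp(0.4 + 0.3 * x))
        data = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(150)], "x": x, "count": y}
        )
        beta = np.array([0.4, 0.3])
        L = marginal_loglik(self.spec, {"beta": beta, "sigma_u": 0.0, "pi": 0.0}, data)
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson())
        assert L == pytest.approx(glm.loglike(beta), abs=1e-8)


class TestFit:
    def test_recovers_poisson_glm_when_degenerate(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = rng.poisson(np.exp(0.5 + 0.4 * x))
        data = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(300)], "x": x, "count": y}
        )
        spec = ModelSpec(
            response="count", fixed_terms=("x",),
            random_intercept_group=None, zero_inflation="none",
        )
        fit = fit_zip_glmm(spec, data)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert fit.converged
        assert np.allclose(fit.beta.to_numpy(), ref.params, atol=1e-5)
        assert np.allclose(fit.se_beta.to_numpy(), ref.bse, rtol=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_zero_inflation_nested_when_pi_is_zero(self):
        rng = np.random.default_rng(4)
        data = make_zip_glmm_data(rng, n_subjects=60, pi=0.0)
        f_zip = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
        f_pois = fit_zip_glmm(
            ModelSpec(response="count", fixed_terms=("x",), zero_inflation="none"), data
        )
        assert f_zip.converged and f_pois.converged
        assert abs(f_zip.loglik - f_pois.loglik) < 2.0
        assert np.allclose(f_zip.beta.to_numpy(), f_pois.beta.to_numpy(), atol=0.01)

    def test_all_zero_response_degenerate_not_exception(self):
        data = pd.DataFrame(
            {"subject": ["a", "a", "b", "b"], "x": [0, 1, 0, 1], "count": [0, 0, 0, 0]}
        )
        fit = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
        assert not fit.converged
        assert fit.beta.isna().all()

    def test_laplace_close_to_quadrature(self):
        rng = np.random.default_rng(5)
        data = make_zip_glmm_data(rng, n_subjects=40)
        f_agq = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
        f_lap = fit_zip_glmm(
            ModelSpec(response="count", fixed_terms=("x",)), data, method="laplace"
        )
        assert f_lap.method == "laplace"
        assert np.allclose(f_agq.beta.to_numpy(), f_lap.beta.to_numpy(), atol=5e-3)

    def test_wald_null_calibration(self):
        """Permuted covariate: |z| > 1.96 in roughly 5% of replicates."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            data = make_zip_glmm_data(rng, n_subjects=40, slope=0.0)
            fit = fit_zip_glmm(
                ModelSpec(response="count", fixed_terms=("x",)), data, method="laplace"
            )
            if fit.converged and abs(fit.beta["x"] / fit.se_beta["x"]) > 1.96:
                rejections += 1
        # 95% binomial band around 0.05 with n=60 (exact binomial: 0..7)
        assert rejections <= 8


class TestLRT:
    def test_identical_models_statistic_zero(self):
        rng = np.random.default_rng(7)
        data = make_zip_glmm_data(rng, n_subjects=30)
        fit = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.pvalue == 1.0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(8)
        data = make_zip_glmm_data(rng, n_subjects=30)
        data["z"] = rng.normal(size=len(data))
        f1 = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
        f2 = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("z",)), data)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f1, f2)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(9)
        detected = 0
        for _ in range(10):
            data = make_zip_glmm_data(rng, n_subjects=50, slope=0.15)
            full = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
            red = fit_zip_glmm(ModelSpec(response="count", fixed_terms=()), data)
            if likelihood_ratio_test(full, red).pvalue < 0.001:
                detected += 1
        assert detected >= 9

    def test_null_term_p_roughly_uniform(self):
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(40):
            data = make_zip_glmm_data(rng, n_subjects=30, slope=0.0)
            full = fit_zip_glmm(
                ModelSpec(response="count", fixed_terms=("x",)), data, method="laplace"
            )
            red = fit_zip_glmm(
                ModelSpec(response="count", fixed_terms=()), data, method="laplace"
            )
            if full.converged and red.converged:
                pvals.append(likelihood_ratio_test(full, red).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPredictMarginalMean:
    def test_closed_form_intercept_only(self):
        data = pd.DataFrame(
            {"subject": list("aabb"), "count": [4, 4, 4, 4]}
        )
        spec = ModelSpec(response="count", fixed_terms=(), zero_inflation="none")
        fit = fit_zip_glmm(spec, data)
        pred = predict_marginal_mean(fit, {"dummy": [0]})
        # sigma is driven to ~0 by identical counts; mean == 4
        assert pred["estimate"].iloc[0] == pytest.approx(4.0, rel=1e-3)

    def test_matches_monte_carlo_average(self):
        rng = np.random.default_rng(11)
        data = make_zip_glmm_data(rng, n_subjects=80, n_trials=6)
        spec = ModelSpec(response="count", fixed_terms=("x",))
        fit = fit_zip_glmm(spec, data)
        pred = predict_marginal_mean(fit, {"x": [1.0]})
        u = rng.normal(0, fit.sigma_u, 10**6)
        mc = (1 - fit.pi) * np.exp(
            fit.beta["Intercept"] + fit.beta["x"] * 1.0 + u
        ).mean()
        assert pred["estimate"].iloc[0] == pytest.approx(mc, rel=0.005)

    def test_zero_coefficient_covariate_is_inert(self):
        rng = np.random.default_rng(12)
        data = make_zip_glmm_data(rng, n_subjects=40)
        fit = fit_zip_glmm(ModelSpec(response="count", fixed_terms=("x",)), data)
        # same x, arbitrary extra columns are ignored by the design
        a = predict_marginal_mean(fit, {"x": [0.7], "unused": [1]})
        b = predict_marginal_mean(fit, {"x": [0.7], "unused": [99]})
        assert a["estimate"].iloc[0] == b["estimate"].iloc[0]


class TestDesignBuilder:
    def test_factor_and_interaction_encoding(self):
        data = pd.DataFrame(
            {"g": ["a", "b", "a", "b"], "x": [1.0, 2.0, 3.0, 4.0]}
        )
        X, names, levels = build_design(data, ["g", "x", "g:x"])
        assert names == ["Intercept", "g[T.b]", "x", "g[T.b]:x"]
        np.testing.assert_allclose(X[:, 1], [0, 1, 0, 1])
        np.testing.assert_allclose(X[:, 3], [0, 2, 0, 4])

    def test_unknown_column_raises(self):
        with pytest.raises(KeyError):
            build_design(pd.DataFrame({"x": [1.0]}), ["y"])
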