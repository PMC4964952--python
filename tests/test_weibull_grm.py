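import numpy as np
import pytest
from scipy import optimize, special

from cengrm import ModelSpec, fit_weibull_grm
from cengrm.weibull_grm import (
    censored_loglik,
    deviance_residuals,
    fit_design,
    generalized_r2,
    multiplicative_effect,
    per_site_loglik,
    score_matrix,
    weibull_moments,
    weibull_probability_points,
)


def simulate_weibull(rng, n, beta, alpha, censor_q=0.3, x_sd=1.0):
    p = len(beta) - 1
    X = np.column_stack([np.ones(n), rng.normal(0, x_sd, (n, p))])
    lam = np.exp(X @ np.asarray(beta)) / special.gamma(1 + 1 / alpha)
    y = lam * rng.weibull(alpha, n)
    dl = np.quantile(y, censor_q) if censor_q else 0.0
    delta = (y >= dl).astype(int)
    t = np.where(delta == 1, y, dl)
    return X, t, delta


class TestMoments:
    def test_exponential_special_case(self):
        m = weibull_moments(1.0, 1.0)
        assert m["pdf"](1.0) == pytest.approx(np.exp(-1))
        assert m["cdf"](1.0) == pytest.approx(1 - np.exp(-1))
        assert m["mean"] == pytest.approx(1.0)
        assert m["variance"] == pytest.approx(1.0)

    def test_half_normal_mean(self):
        assert weibull_moments(2.0, 1.0)["mean"] == pytest.approx(
            np.sqrt(np.pi) / 2)

    def test_cdf_zero_below_support(self):
        assert weibull_moments(1.5, 2.0)["cdf"](-1.0) == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            weibull_moments(0.0, 1.0)


class TestCensoredLoglik:
    def test_single_uncensored_unit(self):
        # alpha=1, lambda=1: log f(1) = -1
        theta = np.array([0.0, 0.0])
        X = np.ones((1, 1))
        assert censored_loglik(theta, X, [1.0], [1]) == pytest.approx(-1.0)

    def test_single_censored_at_half(self):
        theta = np.array([0.0, 0.0])
        X = np.ones((1, 1))
        expected = np.log(1 - np.exp(-0.5))
        assert censored_loglik(theta, X, [0.5], [0]) == pytest.approx(
            expected, abs=1e-10)

    def test_matches_term_by_term_sum(self, rng):
        # brute-force per-observation evaluation without the vectorised path
        X, t, delta = simulate_weibull(rng, 20, [0.5, 0.3], 1.3)
        theta = np.array([0.4, 0.25, np.log(1.2)])
        alpha = 1.2
        total = 0.0
        for i in range(20):
            lam = np.exp(X[i] @ theta[:2]) / special.gamma(1 + 1 / alpha)
            if delta[i] == 1:
                total += np.log(
                    (alpha / lam) * (t[i] / lam) ** (alpha - 1)
                    * np.exp(-((t[i] / lam) ** alpha)))
            else:
                total += np.log(1 - np.exp(-((t[i] / lam) ** alpha)))
        assert censored_loglik(theta, X, t, delta) == pytest.approx(total)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        X, t, delta = simulate_weibull(rng, 50, [1.0, -0.4, 0.2], 0.9)
        theta = np.array([0.8, -0.3, 0.1, 0.3])
        g = score_matrix(theta, X, t, delta).sum(axis=0)
        g_fd = optimize.approx_fprime(
            theta, lambda th: censored_loglik(th, X, t, delta), 1e-7)
        np.testing.assert_allclose(g, g_fd, rtol=1e-4, atol=1e-4)

    def test_zero_threshold_flagged(self):
        theta = np.array([0.0, 0.0])
        with pytest.raises(ValueError, match="nonpositive detection limit"):
            censored_loglik(theta, np.ones((1, 1)), [0.0], [0])


class TestFit:
    def test_exponential_closed_form_intercept(self, rng):
        y = rng.exponential(3.0, 400)
        fit = fit_design(np.ones((400, 1)), y, np.ones(400, int),
                         fix_alpha=1.0)
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_recovers_truth_within_three_se(self, rng):
        beta = [1.2, 0.5, -0.3]
        X, t, delta = simulate_weibull(rng, 2000, beta, 1.5)
        fit = fit_design(X, t, delta)
        se = fit.se()
        for j in range(3):
            assert abs(fit.beta[j] - beta[j]) < 3 * se[j]
        assert fit.alpha_hat == pytest.approx(1.5, rel=0.1)

    def test_matches_lifelines_aft(self, rng):
        # independent survival-regression oracle: left-censored Weibull AFT
        # with log-scale link; slopes agree, intercepts differ by
        # log Gamma(1 + 1/alpha_hat)
        import pandas as pd
        from lifelines import WeibullAFTFitter

        X, t, delta = simulate_weibull(rng, 800, [1.0, 0.4], 1.3)
        fit = fit_design(X, t, delta)
        df = pd.DataFrame({"t": t, "x": X[:, 1], "E": delta})
        aft = WeibullAFTFitter()
        aft.fit_left_censoring(df, "t", "E")
        assert fit.alpha_hat == pytest.approx(
            np.exp(aft.params_["rho_"]["Intercept"]), rel=1e-4)
        assert fit.beta[1] == pytest.approx(
            aft.params_["lambda_"]["x"], abs=1e-5)
        shift = special.gammaln(1 + 1 / fit.alpha_hat)
        assert fit.beta[0] == pytest.approx(
            aft.params_["lambda_"]["Intercept"] + shift, abs=1e-5)

    def test_constant_column_shifts_only_intercept(self, rng):
        X, t, delta = simulate_weibull(rng, 600, [1.0, 0.3], 1.2)
        fit_a = fit_design(X, t, delta)
        Xc = X.copy()
        Xc[:, 0] = 2.0  # intercept column scaled: same span
        fit_b = fit_design(Xc, t, delta)
        assert fit_b.beta[0] * 2.0 == pytest.approx(fit_a.beta[0], abs=1e-6)
        assert fit_b.beta[1] == pytest.approx(fit_a.beta[1], abs=1e-6)
        assert fit_b.alpha_hat == pytest.approx(fit_a.alpha_hat, rel=1e-6)

    def test_common_cv_across_sites(self, rng):
        # fitted per-site distributions share the CV implied by alpha_hat
        X, t, delta = simulate_weibull(rng, 500, [1.0, 0.5], 1.4)
        fit = fit_design(X, t, delta)
        a = fit.alpha_hat
        cv = np.sqrt(special.gamma(1 + 2 / a)
                     / special.gamma(1 + 1 / a) ** 2 - 1)
        lam = fit.fitted_mu / special.gamma(1 + 1 / a)
        site_cv = np.sqrt(lam**2 * special.gamma(1 + 2 / a)
                          - fit.fitted_mu**2) / fit.fitted_mu
        np.testing.assert_allclose(site_cv, cv, rtol=1e-10)

    def test_no_uncensored_rejected(self):
        with pytest.raises(ValueError):
            fit_design(np.ones((3, 1)), [1, 1, 1.0], [0, 0, 0])


class TestEffects:
    def test_paper_style_conventions(self):
        eff = multiplicative_effect(-0.023)
        assert eff["factor"] == pytest.approx(0.977, abs=5e-4)
        assert eff["percent_change_abs_beta"] == pytest.approx(2.3)
        eff2 = multiplicative_effect(-0.025, 0.148)
        assert eff2["factor"] == pytest.approx(np.exp(0.123))
        assert eff2["percent_change_exact"] == pytest.approx(13.0, abs=0.2)

    def test_null_effect(self):
        eff = multiplicative_effect(0.0)
        assert eff["factor"] == 1.0
        assert eff["percent_change_exact"] == 0.0
        assert eff["direction"] == "none"


class TestDiagnostics:
    def test_deviance_residual_landmarks(self, rng):
        X, t, delta = simulate_weibull(rng, 200, [1.0], 1.0, censor_q=0.2)
        fit = fit_design(X, t, delta)
        lam = fit.fitted_mu / special.gamma(1 + 1 / fit.alpha_hat)
        # uncensored site with unit cumulative hazard -> residual 0
        t0 = lam[0]
        d = deviance_residuals(fit, np.array([t0]), np.array([1]))
        assert d[0] == pytest.approx(0.0, abs=1e-10)
        # uncensored site with cumulative hazard 2
        t2 = lam[0] * 2 ** (1 / fit.alpha_hat)
        d = deviance_residuals(fit, np.array([t2]), np.array([1]))
        assert d[0] == pytest.approx(-np.sqrt(2 * (1 - np.log(2))), abs=1e-8)
        # censored site with zero hazard contributes nothing
        d = deviance_residuals(fit, np.array([1e-300]), np.array([0]))
        assert d[0] == pytest.approx(0.0, abs=1e-6)

    def test_most_residuals_within_two(self, rng):
        X, t, delta = simulate_weibull(rng, 1500, [1.0, 0.4], 1.5)
        fit = fit_design(X, t, delta)
        d = deviance_residuals(fit, t, delta)
        assert 0.90 < np.mean(np.abs(d) <= 2) <= 1.0

    def test_generalized_r2_bounds(self):
        assert generalized_r2(-100.0, -100.0, 50) == 0.0
        assert 0 < generalized_r2(-80.0, -100.0, 50) < 1
        with pytest.raises(ValueError):
            generalized_r2(-80.0, -100.0, 0)

    def test_probability_plot_slope_estimates_shape(self, rng):
        for alpha, lo, hi in [(2.0, 1.8, 2.2), (1.0, 0.9, 1.1)]:
            y = rng.weibull(alpha, 2000) * 3.0
            dl = np.quantile(y, 0.2)
            delta = (y >= dl).astype(int)
            t = np.where(delta == 1, y, dl)
            _, _, slope = weibull_probability_points(t, delta)
            assert lo < slope < hi

    def test_unit_cdf_point_has_zero_ordinate(self, rng):
        y = rng.weibull(1.0, 500)
        x, ords, _ = weibull_probability_points(y, np.ones(500, int))
        # at F = 1 - 1/e the ordinate log(-log(1-F)) crosses zero
        j = np.argmin(np.abs(ords))
        # with n=500 some point sits essentially on the crossing, and its
        # abscissa is near log(scale)=0 for a unit exponential
        assert abs(ords[j]) < 0.05
        assert abs(x[j]) < 0.3

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            weibull_probability_points([1, 1, 1, 2.0], [1, 1, 1, 1])


def test_fit_from_dataset_spec(small_dataset):
    fit = fit_weibull_grm(ModelSpec(continuous_terms=("tssc",)), small_dataset)
    assert fit.convergence["status"] in ("converged", "loose-gradient")
    assert fit.p == 2
    assert np.isfinite(fit.loglik)
    cov = fit.naive_cov[:2, :2]
    assert np.all(np.linalg.eigvalsh(0.5 * (cov + cov.T)) > -1e-10)
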