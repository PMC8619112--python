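"""Score/Hessian correctness, Newton and profile-grid fitting, Wald inference."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from abrelates import (
    FitOptions,
    Theta,
    TrialData,
    benchmark_design,
    fit,
    fit_logistic,
    generate_dataset,
    hessian,
    log_likelihood,
    newton_raphson,
    predict_prob,
    profile_fit_g2,
    score,
    wald_inference,
)
from abrelates.model import CodingScheme

from conftest import random_data, random_theta


def loglik_of_vector(data):
    g, p = data.g, data.p
    return lambda v: log_likelihood(Theta.from_vector(v, g, p), data)


class TestDerivatives:
    def test_score_matches_finite_differences(self, rng):
        for _ in range(20):
            data = random_data(rng, n=50)
            theta = random_theta(rng)
            s = score(theta, data)
            fd = approx_fprime(theta.as_vector(), loglik_of_vector(data), 1e-6)
            np.testing.assert_allclose(s, fd, rtol=1e-5, atol=1e-5)

    def test_score_sum_zero_coding(self, rng):
        data = random_data(rng, n=50, coding="sum_zero")
        theta = random_theta(rng)
        fd = approx_fprime(theta.as_vector(), loglik_of_vector(data), 1e-6)
        np.testing.assert_allclose(score(theta, data), fd, rtol=1e-5, atol=1e-5)

    def test_score_delta_zero_reduces_to_logistic_score(self, rng):
        data = random_data(rng, n=60)
        th = random_theta(rng)
        th0 = Theta(th.mu, th.tau, th.beta, np.zeros(1))
        V = data.design()
        lp = V @ th0.beta_star()
        resid = data.y - 1.0 / (1.0 + np.exp(-lp))
        np.testing.assert_allclose(score(th0, data)[:-1], V.T @ resid, atol=1e-10)

    def test_hessian_matches_fd_jacobian_of_score(self, rng):
        for _ in range(5):
            data = random_data(rng, n=40)
            theta = random_theta(rng)
            H = hessian(theta, data)
            v0 = theta.as_vector()
            fd = np.array(
                [
                    approx_fprime(
                        v0,
                        lambda v, k=k: score(
                            Theta.from_vector(v, data.g, data.p), data
                        )[k],
                        1e-6,
                    )
                    for k in range(v0.size)
                ]
            )
            np.testing.assert_allclose(H, fd, rtol=1e-4, atol=1e-4)
            np.testing.assert_allclose(H, H.T, atol=1e-12)

    def test_hessian_delta_zero_block_is_weighted_outer_product(self, rng):
        data = random_data(rng, n=50)
        th = random_theta(rng)
        th0 = Theta(th.mu, th.tau, th.beta, np.zeros(1))
        V = data.design()
        pi = 1.0 / (1.0 + np.exp(-(V @ th0.beta_star())))
        w = pi * (1 - pi)
        np.testing.assert_allclose(
            hessian(th0, data)[:-1, :-1], -(V * w[:, None]).T @ V, atol=1e-10
        )

    def test_score_vanishes_at_mle(self, rng):
        data = generate_dataset(benchmark_design(500, seed=3))
        res = fit(data, FitOptions(grid_points=41))
        assert res.converged
        assert np.max(np.abs(score(res.theta, data))) < 1e-6


class TestLogisticFit:
    def test_matches_statsmodels_irls(self, rng):
        import statsmodels.api as sm

        data = generate_dataset(benchmark_design(800, delta1=0.0, seed=5))
        res = fit_logistic(data)
        D = data.design()
        oracle = sm.GLM(data.y, D, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res.estimates, oracle.params, atol=1e-6)
        np.testing.assert_allclose(res.se, oracle.bse, rtol=1e-4)
        assert res.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_no_intercept_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        data = generate_dataset(benchmark_design(600, delta1=0.0, seed=6))
        res = fit_logistic(data, FitOptions(fix_mu_zero=True))
        D = data.design()[:, 1:]
        oracle = sm.GLM(data.y, D, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res.estimates, oracle.params, atol=1e-6)
        assert res.theta.mu == 0.0

    def test_perfect_separation_is_flagged(self):
        x = np.linspace(-2, 2, 40)
        data = TrialData(
            y=(x > 0).astype(float),
            group=np.tile([1, 2], 20),
            X=x[:, None],
            g=2,
        )
        res = fit_logistic(data, FitOptions(max_iter=60))
        assert (not res.converged) or any("separation" in w for w in res.warnings)


class TestProfileFit:
    def test_trace_argmax_is_selected_grid_point(self, rng):
        data = generate_dataset(benchmark_design(400, seed=8))
        res = profile_fit_g2(data, FitOptions(grid_points=41))
        deltas, lls = zip(*res.grid_trace)
        assert deltas[int(np.argmax(lls))] == pytest.approx(res.selected_grid_delta)

    def test_null_delta_recovery(self, rng):
        data = generate_dataset(benchmark_design(2000, delta1=0.0, seed=9))
        res = profile_fit_g2(data, FitOptions(grid_points=41, fix_mu_zero=True))
        spacing = 1.98 / 40
        se = res.stderr("delta1")
        assert abs(res.estimate("delta1")) < spacing + 3 * se

    def test_likelihood_dominates_delta_zero_fit(self, rng):
        for seed in (1, 2, 3):
            data = generate_dataset(benchmark_design(300, seed=seed))
            full = fit(data, FitOptions(grid_points=41))
            reduced = fit_logistic(data)
            assert full.loglik >= reduced.loglik - 1e-8

    def test_fitted_loglik_beats_truth(self):
        design = benchmark_design(1000, seed=10)
        data = generate_dataset(design)
        res = fit(data, FitOptions(grid_points=41))
        assert res.loglik >= log_likelihood(design.true_theta(), data)

    def test_polish_improves_on_grid(self, rng):
        data = generate_dataset(benchmark_design(500, seed=11))
        res = profile_fit_g2(data, FitOptions(grid_points=21))
        best_grid_ll = max(ll for _, ll in res.grid_trace)
        assert res.loglik >= best_grid_ll - 1e-10

    def test_control_relabel_invariance(self):
        """Swapping which arm is control is a reparameterization: fitted
        probabilities are unchanged (delta' = -delta/(1+delta) stays in
        range for the moderate delta used here)."""
        design = benchmark_design(600, delta1=-0.3, seed=12)
        data = generate_dataset(design)
        opts = FitOptions(grid_points=41, score_tol=1e-10)
        res = fit(data, opts)
        swapped = TrialData(
            y=data.y,
            group=np.where(data.group == 1, 2, 1),
            X=data.X,
            coding=data.coding,
            g=2,
        )
        res2 = fit(swapped, opts)
        np.testing.assert_allclose(
            predict_prob(res.theta, data),
            predict_prob(res2.theta, swapped),
            atol=1e-8,
        )


class TestWaldInference:
    def test_se_positive_and_ci_brackets_estimate(self, rng):
        data = generate_dataset(benchmark_design(500, seed=13))
        res = fit(data, FitOptions(grid_points=41))
        assert np.all(res.se > 0)
        assert np.all(res.ci_low < res.estimates) and np.all(res.estimates < res.ci_high)
        assert np.all((res.p_value >= 0) & (res.p_value <= 1))
        wide = wald_inference(res, level=0.99)
        assert np.all(wide.ci_high - wide.ci_low > 0)

    def test_se_agrees_with_bootstrap(self, rng):
        """Observed-information SE vs nonparametric bootstrap on one dataset."""
        data = generate_dataset(benchmark_design(500, seed=14))
        opts = FitOptions(grid_points=41, fix_mu_zero=True)
        res = fit(data, opts)
        boot = []
        for _ in range(200):
            ix = rng.integers(0, data.n, size=data.n)
            if len(np.unique(data.group[ix])) < 2:
                continue
            bd = TrialData(
                y=data.y[ix], group=data.group[ix], X=data.X[ix], coding=data.coding, g=2
            )
            try:
                b = fit(bd, opts)
            except Exception:
                continue
            if b.converged:
                boot.append(b.estimate("delta1"))
        boot_se = np.std(boot, ddof=1)
        assert res.stderr("delta1") == pytest.approx(boot_se, rel=0.25)


class TestFullNewton:
    def test_matches_profile_fit(self):
        data = generate_dataset(benchmark_design(800, seed=15))
        prof = profile_fit_g2(data, FitOptions(grid_points=41))
        full = newton_raphson(data, None, FitOptions(method="full_newton"))
        assert full.converged
        assert full.loglik == pytest.approx(prof.loglik, abs=1e-6)
        np.testing.assert_allclose(
            full.theta.as_vector(), prof.theta.as_vector(), atol=1e-4
        )

    def test_three_arm_fit_recovers_parameters(self, rng):
        from abrelates import CovariateSpec, SimDesign

        design = SimDesign(
            n=3000,
            g=3,
            tau0=(-1.0, 0.5),
            beta0=(-0.5, 0.5),
            delta0=(-0.3, 0.2),
            covariates=(CovariateSpec(), CovariateSpec()),
            seed=16,
        )
        data = generate_dataset(design)
        res = fit(data, FitOptions(method="full_newton", fix_mu_zero=True))
        assert res.converged
        for name, truth in [("tau1", -1.0), ("tau2", 0.5), ("delta1", -0.3), ("delta2", 0.2)]:
            est, se = res.estimate(name), res.stderr(name)
            assert abs(est - truth) < 4 * se, (name, est, se)
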