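"""Conjugate draws: NIG regression posterior, predictive draws, NIW
posterior, conditional-MVN imputation draws.

Oracles: a dense grid integration of the unnormalized posterior, an OLS fit
under a diffuse prior, the matrix-inversion-lemma form of the posterior
inverse-gamma parameters (an algebraic route independent of the
implementation's), and closed-form conjugate means.
"""

import numpy as np
import pytest
from scipy import stats

from fcsimpute import (
    NIGPrior,
    NIWPrior,
    RegressionData,
    RngStream,
    ThetaConditional,
    ThetaJoint,
    draw_mis_given_theta,
    draw_nig_posterior,
    draw_niw_posterior,
    draw_predictive_normal,
)

from conftest import random_spd


def toy_regression(n=20, seed=99, slope=2.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, size=n)
    y = 1.0 + slope * x + rng.standard_normal(n) * 0.8
    return RegressionData(y, np.column_stack([np.ones(n), x]))


def toy_prior():
    return NIGPrior(
        sigma_df=3.0,
        sigma_scale=2.0,
        coef_mean=np.zeros(2),
        coef_scale=2.0 * np.diag([0.5, 0.5]),
    )


class TestNigPosterior:
    def test_dominating_prior_collapses_to_prior_mean(self, rng):
        data = toy_regression()
        prior = NIGPrior(3.0, 1.0, np.array([5.0, -1.0]), 1e14 * np.eye(2))
        draws = np.array(
            [draw_nig_posterior(data, prior, rng).coef for _ in range(200)]
        )
        assert draws.std(axis=0).max() < 1e-6
        np.testing.assert_allclose(draws.mean(axis=0), [5.0, -1.0], atol=1e-6)

    def test_diffuse_prior_matches_ols(self, rng):
        """Under a near-flat prior the posterior centers on the OLS fit."""
        import statsmodels.api as sm

        gen = np.random.default_rng(31)
        n = 200
        x = gen.uniform(0, 4, size=n)
        y = 3.0 - 1.5 * x + gen.standard_normal(n)
        data = RegressionData(y, np.column_stack([np.ones(n), x]))
        prior = NIGPrior(0.02, 1e-6, np.zeros(2), 1e-6 * 1e-8 * np.eye(2))
        ndraw = 4000
        draws = np.array(
            [draw_nig_posterior(data, prior, rng).coef for _ in range(ndraw)]
        )
        ols = sm.OLS(y, data.X).fit()
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(ndraw)
        assert np.all(np.abs(draws.mean(axis=0) - ols.params) < 3 * mc_se)

    def test_moments_match_grid_integration(self, rng):
        """Posterior moments of (alpha, beta, sigma) agree with a dense grid
        evaluation of the unnormalized posterior (independent oracle)."""
        data = toy_regression()
        prior = toy_prior()
        ndraw = 10_000
        draws = [draw_nig_posterior(data, prior, rng) for _ in range(ndraw)]
        coefs = np.array([d.coef for d in draws])
        sigmas = np.array([d.sigma for d in draws])

        grid_mean, grid_var, grid_sig_mean = _grid_posterior_moments(data, prior)
        rel = np.abs(coefs.mean(axis=0) - grid_mean) / np.abs(grid_mean)
        assert rel.max() < 0.02
        rel_var = np.abs(coefs.var(axis=0, ddof=1) - grid_var) / grid_var
        assert rel_var.max() < 0.05
        assert abs(sigmas.mean() - grid_sig_mean) / grid_sig_mean < 0.02

    def test_sigma_draws_pass_ks_against_analytic_posterior(self, rng):
        """The sigma marginal is InvGamma(a0 + n/2, b0 + SSE_prior/2) where the
        prior-weighted SSE comes from the matrix inversion lemma — an
        algebraic route independent of the implementation's update."""
        data = toy_regression()
        prior = toy_prior()
        n = data.y.size
        a0, b0 = prior.sigma_df / 2.0, prior.sigma_scale / 2.0
        resid0 = data.y - data.X @ prior.coef_mean
        M = np.eye(n) + data.X @ np.linalg.inv(prior.coef_precision) @ data.X.T
        bn = b0 + 0.5 * resid0 @ np.linalg.solve(M, resid0)
        an = a0 + n / 2.0
        sigmas = np.array(
            [draw_nig_posterior(data, prior, rng).sigma for _ in range(10_000)]
        )
        res = stats.kstest(sigmas, stats.invgamma(an, scale=bn).cdf)
        assert res.pvalue > 0.01

    def test_seed_reproducibility(self):
        data = toy_regression()
        prior = toy_prior()
        a = draw_nig_posterior(data, prior, RngStream(7, (1,)))
        b = draw_nig_posterior(data, prior, RngStream(7, (1,)))
        assert a.alpha == b.alpha and a.sigma == b.sigma
        np.testing.assert_array_equal(a.beta, b.beta)


def _grid_posterior_moments(data: RegressionData, prior: NIGPrior):
    """Dense-grid integration of prior x likelihood over (alpha, beta, sigma)."""
    ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    resid = data.y - data.X @ ols
    s2 = resid @ resid / (data.y.size - 2)
    se = np.sqrt(s2 * np.diag(np.linalg.inv(data.X.T @ data.X)))
    alphas = np.linspace(ols[0] - 8 * se[0], ols[0] + 8 * se[0], 90)
    betas = np.linspace(ols[1] - 8 * se[1], ols[1] + 8 * se[1], 90)
    sigmas = np.linspace(s2 / 5, s2 * 6, 160)
    A, B, S = np.meshgrid(alphas, betas, sigmas, indexing="ij")
    # log prior
    P = prior.coef_precision
    g0 = prior.coef_mean
    da, db = A - g0[0], B - g0[1]
    quad_prior = P[0, 0] * da**2 + 2 * P[0, 1] * da * db + P[1, 1] * db**2
    a0, b0 = prior.sigma_df / 2.0, prior.sigma_scale / 2.0
    logp = -(a0 + 1) * np.log(S) - b0 / S  # inverse-gamma kernel
    logp += -np.log(S) - quad_prior / (2 * S)  # coef normal kernel (p=2)
    # log likelihood via sufficient statistics
    n = data.y.size
    sy2 = data.y @ data.y
    sxy = data.X.T @ data.y
    G = data.X.T @ data.X
    sse = (
        sy2
        - 2 * (A * sxy[0] + B * sxy[1])
        + G[0, 0] * A**2
        + 2 * G[0, 1] * A * B
        + G[1, 1] * B**2
    )
    logp += -(n / 2.0) * np.log(S) - sse / (2 * S)
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean = np.array([(w * A).sum(), (w * B).sum()])
    var = np.array([(w * A**2).sum(), (w * B**2).sum()]) - mean**2
    sig_mean = (w * S).sum()
    return mean, var, sig_mean


class TestPredictiveNormal:
    def test_zero_variance_is_deterministic(self, rng):
        theta = ThetaConditional(1.0, np.array([2.0]), 0.0)
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        out = draw_predictive_normal(X, theta, rng)
        np.testing.assert_array_equal(out, X @ theta.coef)

    def test_sample_moments(self):
        theta = ThetaConditional(4.0, np.array([0.0]), 1.0)
        X = np.column_stack([np.ones(100_000), np.zeros(100_000)])
        out = draw_predictive_normal(X, theta, RngStream(5))
        assert abs(out.mean() - 4.0) < 0.01
        assert abs(out.var(ddof=1) - 1.0) < 0.02

    def test_seed_reproducibility(self):
        theta = ThetaConditional(0.0, np.array([1.0]), 2.0)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        a = draw_predictive_normal(X, theta, RngStream(3, (2,)))
        b = draw_predictive_normal(X, theta, RngStream(3, (2,)))
        np.testing.assert_array_equal(a, b)


class TestNiwPosterior:
    def test_dominating_tau_collapses_mu_to_prior_location(self, rng):
        data = np.random.default_rng(0).standard_normal((50, 3)) + 2.0
        prior = NIWPrior(np.array([9.0, 9.0, 9.0]), 1e12, 5.0, np.eye(3))
        draws = np.array([draw_niw_posterior(data, prior, rng).mu for _ in range(50)])
        np.testing.assert_allclose(draws.mean(axis=0), 9.0 * np.ones(3), atol=1e-3)

    def test_consistency_at_large_n(self, rng, sim_prior, sim_mu, sim_sigma):
        n = 10_000
        data = stats.multivariate_normal.rvs(
            sim_mu, sim_sigma, size=n, random_state=np.random.default_rng(8)
        )
        draws = np.array(
            [draw_niw_posterior(data, sim_prior, rng).mu for _ in range(300)]
        )
        se = np.sqrt(np.diag(sim_sigma) / n) + draws.std(axis=0, ddof=1) / np.sqrt(300)
        assert np.all(np.abs(draws.mean(axis=0) - sim_mu) < 3 * se)

    def test_univariate_reduces_to_scalar_conjugate_update(self, rng):
        """p = 1 matches the normal-inverse-gamma update computed by hand."""
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        prior = NIWPrior(np.array([0.0]), 2.0, 3.0, np.array([[4.0]]))
        n, ybar = y.size, y.mean()
        tau_n = 2.0 + n
        mu_n = n * ybar / tau_n
        nu_n = 3.0 + n
        psi_n = 4.0 + ((y - ybar) ** 2).sum() + (2.0 * n / tau_n) * ybar**2
        draws = [draw_niw_posterior(y[:, None], prior, rng) for _ in range(8000)]
        mus = np.array([d.mu[0] for d in draws])
        sigs = np.array([d.Sigma[0, 0] for d in draws])
        # sigma ~ InvGamma(nu_n/2, psi_n/2); mu | sigma ~ N(mu_n, sigma/tau_n)
        assert mus.mean() == pytest.approx(mu_n, abs=4 * mus.std() / np.sqrt(8000))
        exp_sig = (psi_n / 2) / (nu_n / 2 - 1)
        assert sigs.mean() == pytest.approx(
            exp_sig, abs=4 * sigs.std() / np.sqrt(8000)
        )
        res = stats.kstest(sigs, stats.invgamma(nu_n / 2, scale=psi_n / 2).cdf)
        assert res.pvalue > 0.01

    def test_seed_reproducibility(self, sim_prior):
        data = np.random.default_rng(1).standard_normal((30, 3))
        a = draw_niw_posterior(data, sim_prior, RngStream(11, (4,)))
        b = draw_niw_posterior(data, sim_prior, RngStream(11, (4,)))
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.Sigma, b.Sigma)

    def test_stationarity_of_alternating_draws(self, sim_prior):
        """P-step draws on complete data are iid posterior draws: the theta
        trace has no drift (Geweke-style z-score on trace halves)."""
        data = np.random.default_rng(2).standard_normal((100, 3)) * 2 + 1
        gen = RngStream(21).generator()
        trace = np.array(
            [draw_niw_posterior(data, sim_prior, gen).mu for _ in range(400)]
        )
        first, second = trace[:200], trace[200:]
        z = (first.mean(axis=0) - second.mean(axis=0)) / np.sqrt(
            first.var(axis=0, ddof=1) / 200 + second.var(axis=0, ddof=1) / 200
        )
        assert np.abs(z).max() < 3


class TestMisGivenTheta:
    def setup_method(self):
        self.theta = ThetaJoint(
            np.array([1.0, 4.0, 9.0]),
            np.array([[4.0, 2.0, 2.0], [2.0, 4.0, 2.0], [2.0, 2.0, 9.0]]),
        )

    def test_fully_observed_returns_empty_block(self, rng):
        out = draw_mis_given_theta(
            np.array([False, False, False]), np.ones((4, 3)), self.theta, rng
        )
        assert out.shape == (4, 0)

    def test_fully_missing_draws_from_joint(self):
        pattern = np.array([True, True, True])
        out = draw_mis_given_theta(
            pattern, np.empty((100_000, 0)), self.theta, RngStream(17)
        )
        se_mu = np.sqrt(np.diag(self.theta.Sigma) / 1e5)
        assert np.all(np.abs(out.mean(axis=0) - self.theta.mu) < 3 * se_mu)
        cov = np.cov(out.T)
        se_cov = 3 * np.abs(self.theta.Sigma) / np.sqrt(1e5) + 0.05
        assert np.all(np.abs(cov - self.theta.Sigma) < 3 * se_cov)

    def test_single_missing_matches_conditional_formula(self, rng):
        """One missing coordinate: the conditional mean/variance equal the
        regression form of the joint parameter."""
        from fcsimpute import theta_joint_to_conditional

        cond, _, _ = theta_joint_to_conditional(self.theta, 1)
        pattern = np.array([False, True, False])
        obs = np.array([[2.0, 7.0]])  # (x, z)
        draws = np.array(
            [
                draw_mis_given_theta(pattern, obs, self.theta, rng)[0, 0]
                for _ in range(20_000)
            ]
        )
        expect_mean = cond.alpha + cond.beta @ obs[0]
        assert draws.mean() == pytest.approx(
            expect_mean, abs=4 * np.sqrt(cond.sigma / 20_000)
        )
        assert draws.var(ddof=1) == pytest.approx(cond.sigma, rel=0.05)

    def test_seed_reproducibility(self):
        pattern = np.array([True, False, False])
        obs = np.array([[4.0, 9.0], [3.0, 8.0]])
        a = draw_mis_given_theta(pattern, obs, self.theta, RngStream(2, (9,)))
        b = draw_mis_given_theta(pattern, obs, self.theta, RngStream(2, (9,)))
        np.testing.assert_array_equal(a, b)
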