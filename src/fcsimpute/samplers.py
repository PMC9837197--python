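"""Exact conjugate posterior draws for the two imputation engines.

Chained-equations imputation needs, per variable and iteration, one draw of
the regression parameters from their normal-inverse-gamma (NIG) posterior
followed by predictive draws for the missing cells; joint-model imputation
needs a draw of (mu, Sigma) from the normal-inverse-Wishart (NIW) posterior
given the completed data followed by conditional multivariate-normal draws
per missing pattern.  All four draws are exact conjugate updates (no inner
MCMC).

The conjugate algebra (documented in the methods note):

NIG regression update, prior ``sigma ~ InvGamma(a0, b0)``,
``gamma | sigma ~ N(g0, sigma * P0^{-1})`` with data ``(y, X)``::

    Pn = P0 + X'X              gn = Pn^{-1} (P0 g0 + X'y)
    an = a0 + n/2              bn = b0 + (y'y + g0'P0 g0 - gn'Pn gn) / 2

NIW update, prior ``Sigma ~ IW(nu, Psi)``, ``mu | Sigma ~ N(mu0, Sigma/tau)``
with completed data (n rows, mean ybar, centered scatter S)::

    nu_n = nu + n              Psi_n = Psi + S + (tau n / (tau+n)) d d',  d = ybar - mu0
    tau_n = tau + n            mu_n = (tau mu0 + n ybar) / (tau + n)

Randomness is plumbed through :class:`RngStream`: one root seed with integer
substream identifiers, so each chain/variable owns an independent,
reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .priors import NIGPrior, NIWPrior, ThetaConditional, ThetaJoint

__all__ = [
    "RngStream",
    "RegressionData",
    "draw_nig_posterior",
    "nig_posterior_params",
    "draw_predictive_normal",
    "draw_niw_posterior",
    "niw_posterior_params",
    "draw_mis_given_theta",
]


@dataclass(frozen=True)
class RngStream:
    """A reproducible random stream: (root seed, substream identifiers).

    Identical ``(seed, stream)`` pairs yield identical draw sequences.
    """

    seed: int
    stream: tuple[int, ...] = ()

    def spawn(self, *ids: int) -> "RngStream":
        return RngStream(self.seed, self.stream + tuple(int(i) for i in ids))

    def generator(self) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), *self.stream])


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, RngStream):
        return rng.generator()
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class RegressionData:
    """Complete response/design pair for one univariate imputation model.

    ``X`` carries a leading column of ones (the intercept).
    """

    y: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("y must be (n,), X must be (n, p) with matching n")
        if y.size < 1:
            raise ValueError("need n >= 1")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("regression data must be complete (finite)")
        if not np.all(X[:, 0] == 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)


def nig_posterior_params(
    data: RegressionData, prior: NIGPrior
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Posterior ``(a_n, b_n, gamma_n, P_n)`` of the NIG regression update."""
    if prior.p != data.X.shape[1]:
        raise ValueError("prior dimension and design width disagree")
    P0 = prior.coef_precision
    g0 = prior.coef_mean
    a0 = prior.sigma_df / 2.0
    b0 = prior.sigma_scale / 2.0
    Pn = P0 + data.X.T @ data.X
    rhs = P0 @ g0 + data.X.T @ data.y
    gn = np.linalg.solve(Pn, rhs)
    an = a0 + data.y.size / 2.0
    bn = b0 + 0.5 * (data.y @ data.y + g0 @ P0 @ g0 - gn @ Pn @ gn)
    return an, float(bn), gn, Pn


def draw_nig_posterior(data: RegressionData, prior: NIGPrior, rng) -> ThetaConditional:
    """One exact draw from the NIG posterior of (alpha, beta, sigma).

    sigma is drawn first from its inverse-gamma full posterior, then the
    coefficients from their conditional normal, matching the prior's
    factorization p(sigma) p(coef | sigma).
    """
    gen = _as_generator(rng)
    an, bn, gn, Pn = nig_posterior_params(data, prior)
    sigma = bn / gen.gamma(an)
    L = np.linalg.cholesky(Pn)
    z = gen.standard_normal(gn.size)
    # cov(L^{-T} z) = Pn^{-1}
    coef = gn + np.sqrt(sigma) * np.linalg.solve(L.T, z)
    return ThetaConditional(coef[0], coef[1:], sigma)


def draw_predictive_normal(Xmis: np.ndarray, theta: ThetaConditional, rng) -> np.ndarray:
    """Independent predictive draws ``N(x_i' (alpha, beta), sigma)``.

    ``sigma`` is a variance; a zero-variance limit returns the linear
    predictor itself.
    """
    gen = _as_generator(rng)
    Xmis = np.asarray(Xmis, dtype=float)
    mean = Xmis @ theta.coef
    if theta.sigma == 0:
        return mean
    return mean + np.sqrt(theta.sigma) * gen.standard_normal(mean.shape)


def niw_posterior_params(
    data: np.ndarray, prior: NIWPrior
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Posterior ``(nu_n, Psi_n, tau_n, mu_n)`` of the NIW update."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != prior.p:
        raise ValueError("data must be (n, p) matching the prior")
    n = data.shape[0]
    if n < 1:
        raise ValueError("need n >= 1")
    if not np.isfinite(data).all():
        raise ValueError("data must be complete (finite)")
    nu, Psi = prior.iw_params()
    ybar = data.mean(axis=0)
    centered = data - ybar
    S = centered.T @ centered
    d = ybar - prior.mu0
    tau_n = prior.tau + n
    nu_n = nu + n
    Psi_n = Psi + S + (prior.tau * n / tau_n) * np.outer(d, d)
    mu_n = (prior.tau * prior.mu0 + n * ybar) / tau_n
    return nu_n, Psi_n, tau_n, mu_n


def draw_niw_posterior(data: np.ndarray, prior: NIWPrior, rng) -> ThetaJoint:
    """One exact draw of (mu, Sigma) from the NIW posterior given complete data."""
    gen = _as_generator(rng)
    nu_n, Psi_n, tau_n, mu_n = niw_posterior_params(data, prior)
    Sigma = stats.invwishart.rvs(df=nu_n, scale=Psi_n, random_state=gen)
    Sigma = np.atleast_2d(Sigma)
    L = np.linalg.cholesky(Sigma / tau_n)
    mu = mu_n + L @ gen.standard_normal(prior.p)
    return ThetaJoint(mu, Sigma)


def draw_mis_given_theta(
    pattern: np.ndarray, observed: np.ndarray, theta: ThetaJoint, rng
) -> np.ndarray:
    """Draw the missing block from the conditional MVN for one missing pattern.

    Parameters
    ----------
    pattern : (p,) bool array
        True where the coordinate is missing (shared by all rows passed).
    observed : (k, n_obs) array
        Observed coordinates of the k rows of this pattern, in column order.
    theta : ThetaJoint
        Current parameter draw.
    rng : Generator or RngStream

    Returns
    -------
    (k, n_mis) array of imputed values (empty when nothing is missing).
    """
    gen = _as_generator(rng)
    pattern = np.asarray(pattern, dtype=bool)
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    k = observed.shape[0]
    mis = np.flatnonzero(pattern)
    obs = np.flatnonzero(~pattern)
    if observed.shape[1] != obs.size:
        raise ValueError("observed block width disagrees with the pattern")
    if mis.size == 0:
        return np.empty((k, 0))
    mu_m = theta.mu[mis]
    if obs.size == 0:
        cond_mean = np.broadcast_to(mu_m, (k, mis.size))
        cond_cov = theta.Sigma[np.ix_(mis, mis)]
    else:
        S_oo = theta.Sigma[np.ix_(obs, obs)]
        S_mo = theta.Sigma[np.ix_(mis, obs)]
        B = np.linalg.solve(S_oo, S_mo.T).T  # regression of mis on obs
        cond_mean = mu_m + (observed - theta.mu[obs]) @ B.T
        cond_cov = theta.Sigma[np.ix_(mis, mis)] - B @ S_mo.T
        cond_cov = (cond_cov + cond_cov.T) / 2.0
    L = np.linalg.cholesky(cond_cov)
    z = gen.standard_normal((k, mis.size))
    return cond_mean + z @ L.T
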