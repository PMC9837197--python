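"""Joint-model imputation for multivariate normal data under an NIW prior.

Data augmentation alternates two exact conjugate draws: the P-step draws
(mu, Sigma) from the NIW posterior given the current completed data and the
I-step redraws every missing block from its conditional multivariate normal,
per missing pattern.  The post-burn-in (mu, Sigma) sample is the joint
Bayesian posterior and serves as the gold standard for the equivalence
check against chained equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcs import ImputationResult, IncompleteData, initialize_fill
from .priors import NIWPrior, ThetaJoint, theta_joint_to_conditional
from .samplers import RngStream, draw_mis_given_theta, draw_niw_posterior

__all__ = ["JMConfig", "JMResult", "JMImputer", "run_jm", "theta_to_regression"]


@dataclass(frozen=True)
class JMConfig:
    """Data-augmentation run configuration (n_iter > burn_in >= 0)."""

    prior: NIWPrior
    n_iter: int = 1010
    burn_in: int = 10
    m: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.m < 1:
            raise ValueError("need m >= 1")


@dataclass
class JMResult:
    """Imputations plus the retained posterior sample of (mu, Sigma)."""

    imputation: ImputationResult
    thetas: list[ThetaJoint]

    def theta_dataframe(self) -> pd.DataFrame:
        """Trace with mu components and the upper triangle of Sigma."""
        cols = self.imputation.data.columns
        p = len(cols)
        rows = []
        for t, th in enumerate(self.thetas):
            rec = {"draw": t}
            rec.update({f"mu_{c}": th.mu[k] for k, c in enumerate(cols)})
            for a in range(p):
                for b in range(a, p):
                    rec[f"Sigma_{cols[a]}_{cols[b]}"] = th.Sigma[a, b]
            rows.append(rec)
        return pd.DataFrame(rows)

    def regression_draws(self, variable: str) -> pd.DataFrame:
        """Posterior draws mapped to the regression scale for one variable."""
        j = self.imputation.data.column_index(variable)
        others = [c for c in self.imputation.data.columns if c != variable]
        return theta_to_regression(self.thetas, j, column_names=others)

    def summary(self) -> pd.DataFrame:
        df = self.theta_dataframe().drop(columns="draw")
        return df.agg(["mean", "std"]).T


def theta_to_regression(
    thetas, j: int, column_names=None
) -> pd.DataFrame:
    """Map (mu, Sigma) draws to the conditional regression of variable j.

    Applies the conditional multivariate-normal formulas draw-wise, so
    joint-model posterior draws can be compared with chained-equations
    parameter traces on the same (alpha, beta, sigma) scale.
    """
    rows = []
    for th in thetas:
        cond, _, _ = theta_joint_to_conditional(th, j)
        rows.append((cond.alpha, *cond.beta, cond.sigma))
    nslopes = len(rows[0]) - 2 if rows else 0
    if column_names is None:
        slope_cols = [f"beta_{k}" for k in range(nslopes)]
    else:
        slope_cols = [f"beta_{c}" for c in column_names]
    return pd.DataFrame(rows, columns=["alpha"] + slope_cols + ["sigma"])


def _pattern_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by identical missing pattern (incomplete rows only)."""
    groups: dict[bytes, list[int]] = {}
    patterns: dict[bytes, np.ndarray] = {}
    for i, row in enumerate(mask):
        if not row.any():
            continue
        key = row.tobytes()
        groups.setdefault(key, []).append(i)
        patterns[key] = row
    return [(patterns[k], np.asarray(v)) for k, v in groups.items()]


def run_jm(data: IncompleteData, config: JMConfig) -> JMResult:
    """Data-augmentation imputation: alternate NIW posterior and I-step draws.

    Post-burn-in theta draws are retained; the m imputed datasets are the
    completed matrices at evenly spaced post-burn-in iterations (spacing
    ``(n_iter - burn_in) / m``) to reduce autocorrelation between them.
    """
    root = RngStream(config.seed)
    gen = root.spawn(0).generator()
    current = initialize_fill(data, root.spawn(1).generator())
    groups = _pattern_groups(data.mask)
    kept = max(config.n_iter - config.burn_in, 1)
    spacing = max(kept // config.m, 1)
    keep_at = {config.burn_in + spacing * (k + 1) for k in range(config.m)}
    keep_at = {min(t, config.n_iter) for t in keep_at}
    thetas: list[ThetaJoint] = []
    completed: list[np.ndarray] = []
    for t in range(1, config.n_iter + 1):
        theta = draw_niw_posterior(current, config.prior, gen)
        for pattern, rows in groups:
            obs_cols = ~pattern
            block = draw_mis_given_theta(
                pattern, current[np.ix_(rows, np.flatnonzero(obs_cols))], theta, gen
            )
            current[np.ix_(rows, np.flatnonzero(pattern))] = block
        if t > config.burn_in:
            thetas.append(theta)
        if t in keep_at:
            completed.append(current.copy())
    imputation = ImputationResult(data, completed, [])
    return JMResult(imputation, thetas)


class JMImputer:
    """Joint-model (multivariate normal + NIW prior) imputation model.

    ``JMImputer(data, prior).fit()`` returns a :class:`JMResult` with the m
    imputed datasets and the posterior sample of (mu, Sigma).
    """

    def __init__(self, data, prior: NIWPrior):
        if isinstance(data, pd.DataFrame):
            data = IncompleteData.from_dataframe(data)
        self.data = data
        self.prior = prior

    def fit(
        self, n_iter: int = 1010, burn_in: int = 10, m: int = 5, seed: int = 0
    ) -> JMResult:
        cfg = JMConfig(self.prior, n_iter=n_iter, burn_in=burn_in, m=m, seed=seed)
        return run_jm(self.data, cfg)
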