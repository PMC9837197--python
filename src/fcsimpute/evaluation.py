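"""Pooling and the validation experiments.

Three experiments demonstrate that chained-equations imputation with the
transformed NIG priors behaves like a proper Bayesian procedure converging
to the joint model:

* a bias/coverage/CI-width table for the mean of y under MCAR and MARr,
  pooled by Rubin's rules over m imputations, against complete-case analysis;
* an order-effect diagnostic: the difference between the y-on-(x, z) slope
  recorded directly after updating z versus directly after updating x, with
  a batch-means standard error and a 95% interval tested against zero;
* a distributional comparison of the chained-equations and joint-model
  posterior samples of the regression parameters (quantile pairs and the
  two-sample Kolmogorov-Smirnov statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fcs import (
    IncompleteData,
    _normalize_priors,
    initialize_fill,
    run_fcs,
    update_variable,
)
from .jm import JMConfig, run_jm
from .missingness import SIM_COLUMNS, SIM_MU, SIM_SIGMA, AmputationSpec, ampute, generate_mvn
from .priors import NIWPrior
from .samplers import RngStream

__all__ = [
    "PooledEstimate",
    "CoverageReport",
    "OrderEffectReport",
    "ComparisonResult",
    "rubin_pool",
    "cca_estimate",
    "coverage_experiment",
    "order_effect_experiment",
    "batch_means_se",
    "posterior_compare",
    "jm_fcs_posterior_draws",
]


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooled estimate with a t-based 95% interval.

    ``qbar`` pools the m point estimates, ``ubar`` the within-imputation
    variances, ``b`` is the between-imputation variance and
    ``T = ubar + (1 + 1/m) b`` the total variance.
    """

    qbar: float
    ubar: float
    b: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _t_interval(q: float, T: float, df: float) -> tuple[float, float]:
    half = (stats.norm.ppf(0.975) if np.isinf(df) else stats.t.ppf(0.975, df)) * np.sqrt(T)
    return q - half, q + half


def rubin_pool(estimates, variances, dfcom: float | None = None) -> PooledEstimate:
    """Pool m point estimates and their variances by Rubin's rules.

    ``dfcom`` is the complete-data degrees of freedom; when given, the
    Barnard-Rubin small-sample adjustment combines it with the classical
    ``(m-1)(1 + 1/r)^2``.  With m = 1 no between-imputation variance can be
    estimated: the within variance is returned as the total (flagged by
    ``b = 0`` and infinite df handling downstream).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise ValueError("need at least one estimate")
    if q.shape != u.shape:
        raise ValueError("estimates and variances disagree in length")
    m = q.size
    qbar = float(q.mean())
    ubar = float(u.mean())
    if m == 1:
        warnings.warn("m = 1: between-imputation variance is not estimable")
        T = ubar
        df = np.inf if dfcom is None else float(dfcom)
        lo, hi = _t_interval(qbar, T, df)
        return PooledEstimate(qbar, ubar, 0.0, T, df, lo, hi, m)
    b = float(q.var(ddof=1))
    T = ubar + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = np.inf if dfcom is None else float(dfcom)
    else:
        r = (1.0 + 1.0 / m) * b / ubar
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2
        if dfcom is None:
            df = df_old
        else:
            gamma = (1.0 + 1.0 / m) * b / T
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - gamma)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    lo, hi = _t_interval(qbar, T, df)
    return PooledEstimate(qbar, ubar, b, T, df, lo, hi, m)


def cca_estimate(data: IncompleteData, column: str) -> PooledEstimate:
    """Complete-case (listwise-deletion) mean with a standard t-interval.

    Returned in the pooled-estimate container (b = 0, m = 1) so the coverage
    experiment can score both methods identically.
    """
    rows = data.complete_rows()
    ncc = int(rows.sum())
    if ncc < 2:
        raise ValueError("need at least 2 complete cases")
    y = data.values[rows, data.column_index(column)]
    mean = float(y.mean())
    var = float(y.var(ddof=1)) / ncc
    df = ncc - 1
    lo, hi = _t_interval(mean, var, df)
    return PooledEstimate(mean, var, 0.0, var, df, lo, hi, 1)


@dataclass
class CoverageReport:
    """Bias / coverage / mean CI width per method, plus per-replication rows."""

    mechanism: str
    n_reps: int
    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = []
        for method, grp in self.records.groupby("method"):
            rows.append(
                {
                    "method": method,
                    "mechanism": self.mechanism,
                    "bias": grp["estimate"].mean() - grp["truth"].iloc[0],
                    "coverage": grp["covers"].mean(),
                    "ci_width": grp["ci_width"].mean(),
                    "n_reps": len(grp),
                }
            )
        return pd.DataFrame(rows).set_index("method")


def coverage_experiment(
    n_reps: int,
    mechanism: str,
    prior: NIWPrior,
    seed: int = 0,
    n: int = 200,
    m: int = 5,
    n_iter: int = 10,
    overall_prop: float = 0.5,
    column: str = "y",
    mu=SIM_MU,
    Sigma=SIM_SIGMA,
    visit_sequence=("z", "x", "y"),
) -> CoverageReport:
    """Repeated-sampling evaluation of the pooled mean of one variable.

    Per replication: generate the trivariate normal sample, ampute, impute by
    chained equations (m chains, n_iter iterations), estimate the mean of
    ``column`` and its variance (sample variance / n) per completed dataset,
    pool by Rubin's rules, and record bias, interval coverage of the true
    mean, and interval width; the same incomplete data are scored by
    complete-case analysis.
    """
    mu = np.asarray(mu, dtype=float)
    truth = float(mu[SIM_COLUMNS.index(column)])
    spec = AmputationSpec(mechanism=mechanism, overall_prop=overall_prop)
    root = RngStream(seed)
    rows = []
    for rep in range(n_reps):
        complete = generate_mvn(n, mu, Sigma, seed=root.spawn(rep, 0))
        data = ampute(complete, spec, seed=root.spawn(rep, 1))
        result = run_fcs(
            data,
            prior,
            visit_sequence=visit_sequence,
            n_iter=n_iter,
            m=m,
            seed=int(root.spawn(rep, 2).generator().integers(2**31)),
            record_trace=False,
        )
        j = data.column_index(column)
        ests, varis = [], []
        for comp in result.completed:
            col = comp[:, j]
            ests.append(col.mean())
            varis.append(col.var(ddof=1) / n)
        pooled = rubin_pool(ests, varis, dfcom=n - 1)
        rows.append(
            {
                "rep": rep,
                "method": "FCS",
                "estimate": pooled.qbar,
                "truth": truth,
                "covers": pooled.covers(truth),
                "ci_width": pooled.ci_width,
            }
        )
        cca = cca_estimate(data, column)
        rows.append(
            {
                "rep": rep,
                "method": "CCA",
                "estimate": cca.qbar,
                "truth": truth,
                "covers": cca.covers(truth),
                "ci_width": cca.ci_width,
            }
        )
    return CoverageReport(mechanism, n_reps, pd.DataFrame(rows))


def batch_means_se(series, n_batches: int = 20) -> float:
    """Batch-means standard error of the mean of a (possibly correlated) series.

    The series is partitioned into ``n_batches`` equal subsequences; the SE is
    the standard deviation of the batch means divided by sqrt(n_batches).  A
    length not divisible by the batch count is truncated at the tail (with a
    warning).  Invariant to adding a constant.
    """
    x = np.asarray(series, dtype=float)
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    if x.size < n_batches:
        raise ValueError("series shorter than the number of batches")
    size = x.size // n_batches
    if x.size % n_batches:
        warnings.warn(
            f"series length {x.size} not divisible by {n_batches} batches; "
            f"truncating to {size * n_batches}"
        )
        x = x[: size * n_batches]
    means = x.reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


@dataclass
class OrderEffectReport:
    """Per-replication order-effect intervals and the exclusion count."""

    n_reps: int
    n_recorded: int
    records: pd.DataFrame

    @property
    def exclusion_count(self) -> int:
        return int(self.records["excludes_zero"].sum())

    @property
    def exclusion_rate(self) -> float:
        return self.exclusion_count / self.n_reps


def order_effect_experiment(
    n_reps: int,
    prior: NIWPrior,
    seed: int = 0,
    n: int = 200,
    burn_in: int = 10,
    n_recorded: int = 1000,
    n_batches: int = 20,
    overall_prop: float = 0.5,
    inject_shift: float = 0.0,
    mu=SIM_MU,
    Sigma=SIM_SIGMA,
) -> OrderEffectReport:
    """Visit-sequence order-effect diagnostic under MCAR missingness.

    Per replication the chained-equations iteration over the visit sequence
    (z, x, y) is augmented: after updating z, an OLS fit of y on (x, z) on
    the completed data records the x-slope ``beta1_z``; after updating x it
    records ``beta1_x``.  Post-burn-in differences ``beta1_z - beta1_x`` are
    collected, their mean is compared against zero with a batch-means 95%
    interval (mean +/- 1.96 SE), and replications whose interval excludes
    zero are counted.  Convergence to a joint distribution implies the two
    estimates share a stationary distribution, so exclusions should be rare.

    ``inject_shift`` adds a constant to x's imputed cells when ``beta1_x`` is
    measured (the chain itself is untouched), making the post-x-update state
    systematically different from the post-z-update state — an artificial
    order effect used as a power check of the diagnostic.
    """
    spec = AmputationSpec(mechanism="MCAR", overall_prop=overall_prop)
    prior_map = None
    root = RngStream(seed)
    rows = []
    zcrit = 1.96
    for rep in range(n_reps):
        complete = generate_mvn(n, mu, Sigma, seed=root.spawn(rep, 0))
        data = ampute(complete, spec, seed=root.spawn(rep, 1))
        if prior_map is None:
            prior_map = _normalize_priors(data, prior)
        jx, jy, jz = (data.column_index(c) for c in ("x", "y", "z"))
        rngs = {j: root.spawn(rep, 2, j).generator() for j in range(data.p)}
        current = initialize_fill(data, root.spawn(rep, 3).generator())
        mask_x = data.mask[:, jx]
        diffs = np.empty(n_recorded)
        for it in range(burn_in + n_recorded):
            update_variable(current, data, jz, prior_map[jz], rngs[jz])
            b1_z = _ols_slope(current, jy, jx, jz)
            update_variable(current, data, jx, prior_map[jx], rngs[jx])
            if inject_shift:
                shifted = current.copy()
                shifted[mask_x, jx] += inject_shift
                b1_x = _ols_slope(shifted, jy, jx, jz)
            else:
                b1_x = _ols_slope(current, jy, jx, jz)
            update_variable(current, data, jy, prior_map[jy], rngs[jy])
            if it >= burn_in:
                diffs[it - burn_in] = b1_z - b1_x
        se = batch_means_se(diffs, n_batches=n_batches)
        mean_diff = float(diffs.mean())
        lo, hi = mean_diff - zcrit * se, mean_diff + zcrit * se
        rows.append(
            {
                "rep": rep,
                "mean_diff": mean_diff,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "excludes_zero": not (lo <= 0.0 <= hi),
            }
        )
    return OrderEffectReport(n_reps, n_recorded, pd.DataFrame(rows))


def _ols_slope(current: np.ndarray, jy: int, jx: int, jz: int) -> float:
    """OLS coefficient of x in the regression y ~ 1 + x + z (normal equations)."""
    X = np.column_stack([np.ones(current.shape[0]), current[:, jx], current[:, jz]])
    coef, *_ = np.linalg.lstsq(X, current[:, jy], rcond=None)
    return float(coef[1])


@dataclass(frozen=True)
class ComparisonResult:
    """Quantile pairs and two-sample KS statistic of two posterior samples."""

    ks_statistic: float
    ks_pvalue: float
    qq: np.ndarray

    @property
    def n(self) -> int:
        return self.qq.shape[0]


def posterior_compare(sample_a, sample_b, n_quantiles: int = 200) -> ComparisonResult:
    """Compare two posterior samples of a scalar parameter.

    Returns evenly spaced quantile pairs (the data behind a QQ plot) and the
    two-sample Kolmogorov-Smirnov statistic; a small statistic means the
    chained-equations and joint-model posteriors are operationally the same.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("posterior samples must be non-empty")
    ks = stats.ks_2samp(a, b)
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    qq = np.column_stack([np.quantile(a, probs), np.quantile(b, probs)])
    return ComparisonResult(float(ks.statistic), float(ks.pvalue), qq)


def jm_fcs_posterior_draws(
    prior: NIWPrior,
    seed: int = 0,
    n: int = 200,
    n_draws: int = 2000,
    burn_in: int = 10,
    variable: str = "y",
    mechanism: str = "MCAR",
    overall_prop: float = 0.5,
    mu=SIM_MU,
    Sigma=SIM_SIGMA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched FCS and JM posterior samples of one variable's regression.

    One amputed dataset is imputed by a single long chained-equations chain
    (parameter trace retained) and by joint-model data augmentation; the JM
    (mu, Sigma) draws are mapped to the regression scale, so both samples
    live on the same (alpha, beta..., sigma) coordinates.
    """
    root = RngStream(seed)
    complete = generate_mvn(n, mu, Sigma, seed=root.spawn(0))
    spec = AmputationSpec(mechanism=mechanism, overall_prop=overall_prop)
    data = ampute(complete, spec, seed=root.spawn(1))
    fcs_res = run_fcs(
        data,
        prior,
        visit_sequence=("z", "x", "y"),
        n_iter=burn_in + n_draws,
        m=1,
        seed=int(root.spawn(2).generator().integers(2**31)),
    )
    fcs_draws = fcs_res.parameter_draws(variable, burn_in=burn_in)
    jm_cfg = JMConfig(
        prior,
        n_iter=burn_in + n_draws,
        burn_in=burn_in,
        m=1,
        seed=int(root.spawn(3).generator().integers(2**31)),
    )
    jm_res = run_jm(data, jm_cfg)
    jm_draws = jm_res.regression_draws(variable)
    return fcs_draws, jm_draws
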