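"""Synthetic trivariate-normal data generation and amputation.

The validation experiments use n = 200 draws from

    (x, y, z) ~ N((1, 4, 9), [[4, 2, 2], [2, 4, 2], [2, 2, 9]])

with fifty percent of the cases made incomplete under three equally likely
one-variable missing patterns (x, y or z missing).  Two mechanisms are
provided: MCAR (missingness independent of the data) and right-tailed MAR
("MARr": within a pattern the probability that the designated variable is
missing increases with the values of the other, observed variables).

MARr functional form: a logistic function of the standardized sum of the
pattern's observed variables (unit weights), with the intercept calibrated
by root finding so the expected within-pattern missing fraction equals the
target proportion.  Missingness depends only on observed coordinates, so the
mechanism is MAR by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .fcs import IncompleteData
from .samplers import RngStream

__all__ = [
    "SIM_MU",
    "SIM_SIGMA",
    "SIM_COLUMNS",
    "AmputationSpec",
    "generate_mvn",
    "ampute",
]

#: mean vector of the simulation's trivariate normal
SIM_MU = np.array([1.0, 4.0, 9.0])
#: covariance matrix of the simulation's trivariate normal
SIM_SIGMA = np.array([[4.0, 2.0, 2.0], [2.0, 4.0, 2.0], [2.0, 2.0, 9.0]])
SIM_COLUMNS = ("x", "y", "z")

MECHANISMS = ("MCAR", "MARr")


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, RngStream):
        return rng.generator()
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_mvn(n: int, mu=SIM_MU, Sigma=SIM_SIGMA, seed=0) -> np.ndarray:
    """n iid draws from N(mu, Sigma); seed-deterministic.

    ``seed`` may be an integer, a Generator, or an RngStream.
    """
    gen = _as_generator(seed)
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if n == 0:
        return np.empty((0, mu.size))
    L = np.linalg.cholesky(Sigma)  # raises on non-SPD
    z = gen.standard_normal((n, mu.size))
    return mu + z @ L.T


@dataclass(frozen=True)
class AmputationSpec:
    """How to make a complete dataset incomplete.

    ``overall_prop`` is the fraction of cases that become incomplete (each
    incomplete case has exactly one missing variable).  ``patterns`` lists
    (missing variable index, weight vector over the other variables); the
    default is one pattern per variable with unit weights, selected with
    equal probability per case.
    """

    mechanism: str = "MCAR"
    overall_prop: float = 0.5
    patterns: tuple[tuple[int, tuple[float, ...]], ...] | None = None
    pattern_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 <= self.overall_prop <= 1.0:
            raise ValueError("overall_prop must be in [0, 1]")
        if self.pattern_probs is not None:
            probs = np.asarray(self.pattern_probs, dtype=float)
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-12:
                raise ValueError("pattern_probs must be non-negative and sum to 1")

    def resolved_patterns(self, p: int):
        if self.patterns is not None:
            return list(self.patterns)
        return [(j, tuple(1.0 for _ in range(p - 1))) for j in range(p)]

    def resolved_probs(self, k: int) -> np.ndarray:
        if self.pattern_probs is not None:
            return np.asarray(self.pattern_probs, dtype=float)
        return np.full(k, 1.0 / k)


def _marr_probs(score: np.ndarray, prop: float) -> np.ndarray:
    """Right-tailed MAR probabilities: expit(a + score), a calibrated so the
    expected missing fraction equals ``prop`` (bisection, tolerance 1e-6)."""
    if prop <= 0.0:
        return np.zeros_like(score)
    if prop >= 1.0:
        return np.ones_like(score)
    sd = score.std()
    s = (score - score.mean()) / (sd if sd > 0 else 1.0)

    def gap(a: float) -> float:
        return float(expit(a + s).mean() - prop)

    a = brentq(gap, -60.0, 60.0, xtol=1e-6)
    return expit(a + s)


def ampute(data, spec: AmputationSpec, seed=0, columns=None) -> IncompleteData:
    """Induce missingness on a complete matrix per the amputation spec.

    Each case is assigned to one pattern (equal probabilities by default);
    within a pattern the designated variable is set missing with probability
    ``overall_prop`` (MCAR) or with the calibrated right-tailed logistic
    probability of the observed-variable score (MARr).  At most one variable
    is missing per case.
    """
    gen = _as_generator(seed)
    values = np.asarray(data, dtype=float)
    n, p = values.shape
    if columns is None:
        columns = SIM_COLUMNS if p == 3 else tuple(f"v{k}" for k in range(p))
    patterns = spec.resolved_patterns(p)
    probs = spec.resolved_probs(len(patterns))
    assignment = gen.choice(len(patterns), size=n, p=probs)
    mask = np.zeros((n, p), dtype=bool)
    for k, (j, weights) in enumerate(patterns):
        rows = np.flatnonzero(assignment == k)
        if rows.size == 0:
            continue
        if spec.mechanism == "MCAR":
            pr = np.full(rows.size, spec.overall_prop)
        else:
            others = [c for c in range(p) if c != j]
            w = np.asarray(weights, dtype=float)
            score = values[np.ix_(rows, others)] @ w
            pr = _marr_probs(score, spec.overall_prop)
        mask[rows, j] = gen.random(rows.size) < pr
    out = values.copy()
    out[mask] = np.nan
    return IncompleteData(out, mask, tuple(columns))
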