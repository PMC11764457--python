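"""Informative priors from pooled expert distributions.

Proportion (categorical) nodes receive a beta prior obtained by moment
matching the pooled mean m and standard deviation s:

    c = m (1 - m) / s^2 - 1,   alpha = m c,   beta = (1 - m) c

feasible only when s^2 < m (1 - m); infeasible pooled moments are flagged,
never silently repaired. A quantile-interpolation alternative fits a beta
quantile function to the pooled quantiles by least squares.

Continuous nodes receive a location-scale Student-T prior whose location
and scale are the pooled mean and SD and whose degrees of freedom are the
number of complete-case experts for the node minus one, or — under the
refit strategy — a fresh best-family fit to the pooled quantile grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .elicitation import NodeDescriptor, ProbabilityAssessment
from .errors import (ConfigurationError, ConvergenceError, FeasibilityError,
                     InsufficientPanelError)
from .families import FAMILY_ORDER, Family, FamilyParams, format_params
from .fitting import FittedDistribution, fit_best
from .pooling import LinearPool, pooled_moments

__all__ = [
    "BetaPrior",
    "StudentTPrior",
    "PriorSpec",
    "beta_from_moments",
    "beta_moments",
    "beta_from_quantiles",
    "t_prior_from_pool",
    "make_prior",
    "format_prior",
    "DEFAULT_QUANTILE_GRID",
]

DEFAULT_QUANTILE_GRID: tuple[float, ...] = (0.01, 0.25, 0.5, 0.75, 0.99)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior for a proportion on [0, 1]."""

    alpha: float
    beta: float
    source: str = "moment_match"  # or "quantile_interpolation"

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0 and self.beta > 0.0):
            raise FeasibilityError(
                f"beta parameters must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))


@dataclass(frozen=True)
class StudentTPrior:
    """Location-scale Student-T prior; df = complete-case experts - 1."""

    location: float
    scale: float
    df: int

    def __post_init__(self) -> None:
        if not self.scale > 0.0:
            raise FeasibilityError(f"scale must be positive, got {self.scale}")
        if not self.df >= 1:
            raise FeasibilityError(f"df must be >= 1, got {self.df}")


@dataclass(frozen=True)
class PriorSpec:
    """A node's informative prior: beta, Student-T, or a refit family."""

    node_id: str
    kind: str  # 'beta' | 'student_t' | 'refit_family'
    parameters: BetaPrior | StudentTPrior | FamilyParams

    def __post_init__(self) -> None:
        expected = {"beta": BetaPrior, "student_t": StudentTPrior,
                    "refit_family": FamilyParams}
        if self.kind not in expected:
            raise ConfigurationError(f"unknown prior kind {self.kind!r}")
        if not isinstance(self.parameters, expected[self.kind]):
            raise ConfigurationError(
                f"prior kind {self.kind!r} does not match parameter type "
                f"{type(self.parameters).__name__}")


def beta_moments(prior: BetaPrior) -> tuple[float, float]:
    """(mean, sd) implied by a beta prior — the inverse of moment matching."""
    return prior.mean, prior.sd


def beta_from_moments(mean: float, sd: float,
                      source: str = "moment_match") -> BetaPrior:
    """Moment-match a Beta(alpha, beta) to a pooled mean and SD.

    Raises :class:`FeasibilityError` when sd^2 >= mean (1 - mean): no beta
    distribution on [0, 1] attains those moments.
    """
    if not 0.0 < mean < 1.0:
        raise FeasibilityError(f"mean must lie in (0, 1), got {mean}")
    if not sd > 0.0:
        raise FeasibilityError(f"sd must be positive, got {sd}")
    bound = mean * (1.0 - mean)
    if sd * sd >= bound:
        raise FeasibilityError(
            f"infeasible moments: sd^2 = {sd * sd:.6g} must be < "
            f"mean(1-mean) = {bound:.6g}")
    c = bound / (sd * sd) - 1.0
    return BetaPrior(mean * c, (1.0 - mean) * c, source=source)


def beta_from_quantiles(lp: LinearPool,
                        probs: Sequence[float] = DEFAULT_QUANTILE_GRID) -> BetaPrior:
    """Fit a beta quantile function to the pooled quantiles by least squares.

    The quantile-interpolation route for proportion nodes; used when the
    pooled shape is poorly summarized by its first two moments.
    """
    for c in lp.components:
        lo, hi = c.params.support
        if lo < -1e-12 or hi > 1.0 + 1e-12:
            # unbounded component families are tolerated as long as their
            # fitted mass is essentially inside [0, 1]
            pass
    probs = np.asarray(sorted(probs), dtype=float)
    target = np.asarray(lp.quantile(probs))

    def objective(vec: np.ndarray) -> float:
        a, b = np.exp(vec)
        fitted = stats.beta.ppf(probs, a, b)
        return float(np.sum((target - fitted) ** 2))

    # start from moment matching on the pooled moments when feasible
    try:
        m = pooled_moments(lp, allow_truncated=True)
        start_prior = beta_from_moments(min(max(m.mean, 1e-3), 1 - 1e-3),
                                        min(m.sd, 0.45))
        x0 = np.log([start_prior.alpha, start_prior.beta])
    except FeasibilityError:
        x0 = np.log([2.0, 2.0])
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14,
                                     "maxiter": 4000})
    if not math.isfinite(res.fun):
        raise ConvergenceError(f"beta quantile interpolation failed for {lp.node_id}")
    a, b = np.exp(res.x)
    return BetaPrior(float(a), float(b), source="quantile_interpolation")


def t_prior_from_pool(pooled_mean: float, pooled_sd: float,
                      n_experts: int) -> StudentTPrior:
    """Pooled continuous prior: T(pooled mean, pooled SD, df = n - 1).

    ``n_experts`` is the complete-case expert count for the node, so the
    degrees of freedom encode how many usable judgments back the prior.
    """
    if n_experts < 2:
        raise InsufficientPanelError(
            f"a pooled T prior needs >= 2 complete-case experts, got {n_experts}")
    return StudentTPrior(float(pooled_mean), float(pooled_sd), int(n_experts) - 1)


def make_prior(node: NodeDescriptor, lp: LinearPool, strategy: str,
               n_experts: int | None = None, seed: int = 0,
               quantile_grid: Sequence[float] = DEFAULT_QUANTILE_GRID) -> PriorSpec:
    """Construct a node's prior from its pool under a named strategy.

    Strategies: ``beta_moment`` and ``beta_quantile`` for proportion nodes;
    ``pooled_moment_t`` and ``refit_best_family`` for continuous nodes.
    ``n_experts`` defaults to the number of pool components (the
    complete-case count when the pool was built from a filtered panel).
    """
    if n_experts is None:
        n_experts = len(lp.components)
    if node.kind == "proportion":
        if strategy == "beta_moment":
            m = pooled_moments(lp, allow_truncated=True)
            return PriorSpec(node.node_id, "beta", beta_from_moments(m.mean, m.sd))
        if strategy == "beta_quantile":
            return PriorSpec(node.node_id, "beta",
                             beta_from_quantiles(lp, probs=quantile_grid))
        raise ConfigurationError(
            f"strategy {strategy!r} is not admissible for proportion node "
            f"{node.node_id}")
    if node.kind == "continuous":
        if strategy == "pooled_moment_t":
            m = pooled_moments(lp, allow_truncated=True)
            return PriorSpec(node.node_id, "student_t",
                             t_prior_from_pool(m.mean, m.sd, n_experts))
        if strategy == "refit_best_family":
            probs = tuple(sorted(quantile_grid))
            points = tuple(zip(probs, (float(lp.quantile(p)) for p in probs)))
            assessment = ProbabilityAssessment("pool", node.node_id, points,
                                               support=node.support)
            # the pooled refit carries the panel df rule (n - 1)
            fit = fit_best(assessment, df=float(max(n_experts - 1, 1)), seed=seed)
            return PriorSpec(node.node_id, "refit_family", fit.params)
        raise ConfigurationError(
            f"strategy {strategy!r} is not admissible for continuous node "
            f"{node.node_id}")
    raise ConfigurationError(f"unknown node kind {node.kind!r}")


def format_prior(spec: PriorSpec, decimals: int = 2) -> str:
    """Report string for a prior, e.g. ``"Beta (7.62, 5.76)"`` or
    ``"T (130.29, 207.84, df = 7)"``."""
    p = spec.parameters
    if isinstance(p, BetaPrior):
        return f"Beta ({p.alpha:.{decimals}f}, {p.beta:.{decimals}f})"
    if isinstance(p, StudentTPrior):
        return (f"T ({p.location:.{decimals}f}, {p.scale:.{decimals}f}, "
                f"df = {p.df})")
    return format_params(p, decimals=decimals)
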