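"""Linear opinion pooling of per-expert fitted distributions.

The pool is the finite mixture f(x) = sum_i w_i f_i(x) over the experts'
best-fit distributions. Experts are equally weighted by default,
regardless of seniority or confidence; unequal weights must be requested
explicitly. Pooled moments are closed-form mixture moments

    mean = sum_i w_i m_i
    var  = sum_i w_i (v_i + m_i^2) - mean^2

and the pooled quantile function inverts the mixture CDF numerically.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ValidationError
from .families import (FAMILY_ORDER, Family, Moments, cdf, density, moments,
                       quantile, sample)
from .fitting import FittedDistribution

__all__ = ["LinearPool", "ConcordanceSummary", "pool", "pooled_moments",
           "concordance"]


@dataclass(frozen=True)
class LinearPool:
    """Equally- (or explicitly-) weighted mixture of per-expert fits."""

    node_id: str
    components: tuple[FittedDistribution, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.components):
            raise ValidationError("one weight per component is required")
        if any(w < 0.0 for w in self.weights):
            raise ValidationError("weights must be non-negative")
        total = sum(self.weights)
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {total}")

    def density(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, c in zip(self.weights, self.components):
            if w > 0.0:
                out = out + w * np.asarray(density(c.params, x))
        return float(out) if out.ndim == 0 else out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, c in zip(self.weights, self.components):
            if w > 0.0:
                out = out + w * np.asarray(cdf(c.params, x))
        return float(out) if out.ndim == 0 else out

    def quantile(self, p):
        """Numeric inversion of the mixture CDF (bracketed bisection).

        The root is bracketed on the union of active-component extreme
        quantiles, which always contains the mixture quantile.
        """
        scalar = np.isscalar(p)
        ps = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any((ps <= 0.0) | (ps >= 1.0)):
            raise ValidationError("pooled quantile requires p in (0, 1)")
        out = np.empty_like(ps)
        active = [c for w, c in zip(self.weights, self.components) if w > 0.0]
        for i, pi in enumerate(ps):
            eps = min(pi, 1.0 - pi, 1e-9)
            lo = min(quantile(c.params, eps) for c in active)
            hi = max(quantile(c.params, 1.0 - eps) for c in active)
            if hi - lo < 1e-300:
                out[i] = lo
                continue
            out[i] = optimize.brentq(lambda x: self.cdf(x) - pi, lo, hi,
                                     xtol=1e-12, rtol=1e-10, maxiter=200)
        return float(out[0]) if scalar else out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.components), size=n, p=np.asarray(self.weights))
        out = np.empty(n)
        for k, c in enumerate(self.components):
            mask = idx == k
            if mask.any():
                out[mask] = sample(c.params, int(mask.sum()), rng)
        return out


@dataclass(frozen=True)
class ConcordanceSummary:
    """Modal best-fit family among the experts for one node (k / n census)."""

    node_id: str
    prevalent_family: Family
    count: int
    total: int

    def __str__(self) -> str:
        from .families import format_family
        return f"{format_family(self.prevalent_family)} ({self.count}/{self.total})"


def pool(fits: list[FittedDistribution],
         weights: list[float] | None = None) -> LinearPool:
    """Build the linear opinion pool for one node's fitted distributions.

    Equal weights are the protocol default; pass ``weights`` only to model
    an explicitly unequal weighting.
    """
    if len(fits) < 2 and weights is None:
        raise ValidationError("pooling requires >= 2 fits (or explicit weights)")
    if not fits:
        raise ValidationError("cannot pool an empty list of fits")
    node_ids = {f.node_id for f in fits}
    if len(node_ids) != 1:
        raise ValidationError(f"fits mix node_ids {sorted(node_ids)}")
    if weights is None:
        weights = [1.0 / len(fits)] * len(fits)
    if len(weights) != len(fits):
        raise ValidationError("one weight per fit is required")
    return LinearPool(fits[0].node_id, tuple(fits), tuple(float(w) for w in weights))


def pooled_moments(lp: LinearPool, allow_truncated: bool = False) -> Moments:
    """Closed-form mixture moments from component moments.

    Components whose moments do not exist (heavy-tailed T-type fits)
    require ``allow_truncated``; the result is then flagged ``truncated``.
    """
    means, variances, methods = [], [], []
    for c in lp.components:
        m = moments(c.params, allow_truncated=allow_truncated)
        means.append(m.mean)
        variances.append(m.sd ** 2)
        methods.append(m.method)
    w = np.asarray(lp.weights)
    means_a = np.asarray(means)
    mean = float(w @ means_a)
    var = float(w @ (np.asarray(variances) + means_a ** 2) - mean ** 2)
    method = "truncated" if "truncated" in methods else "closed_form"
    return Moments(mean, math.sqrt(max(var, 0.0)), method)


def concordance(fits: list[FittedDistribution]) -> ConcordanceSummary:
    """Family census of per-expert best fits; ties go to precedence order."""
    if not fits:
        raise ValidationError("concordance requires at least one fit")
    node_ids = {f.node_id for f in fits}
    if len(node_ids) != 1:
        raise ValidationError(f"fits mix node_ids {sorted(node_ids)}")
    counts = Counter(f.params.family for f in fits)
    top = max(counts.values())
    prevalent = next(f for f in FAMILY_ORDER if counts.get(f, 0) == top)
    return ConcordanceSummary(fits[0].node_id, prevalent, top, len(fits))
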