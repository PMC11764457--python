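"""Least-squares fitting of candidate families to elicited quantiles.

For each candidate family the parameter vector minimizing

    SSE(theta) = sum_j (q_j - Q(p_j; theta))^2

over the assessment's (p_j, q_j) points is found by trust-region least
squares (on an unconstrained reparameterization: positive parameters are
log-transformed) from a moment-matched starting point plus seeded jittered
restarts, with a Nelder–Mead polish when the residual landscape defeats
the gradient-based step. The best-fitting family is the admissible one
with the lowest SSE; near-ties go to the earlier family in the fixed
precedence order normal, T, shifted gamma, mirror gamma, lognormal, log-T,
mirror log-T, shifted-scaled beta.

Mirror (reflected) families need a finite upper anchor and shifted families
a finite lower anchor. When the node support does not supply one, the
elicited extreme value stands in by default (``bound_policy='elicited'``),
which is how left-skewed mirror fits arise on nominally unbounded clinical
quantities; ``bound_policy='support'`` restricts anchors to catalog bounds.

Degrees of freedom for per-expert T-type fits are fixed (default 3, a
conventional heavy-tail elicitation default) rather than estimated from
three to five points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .elicitation import ProbabilityAssessment
from .errors import ConvergenceError, NoFitError, ValidationError
from .families import (FAMILY_ORDER, Family, FamilyParams, quantile)

__all__ = ["FittedDistribution", "fit_family", "fit_best", "sse"]

_NEEDS_LOWER = {Family.SHIFTED_GAMMA, Family.LOGNORMAL, Family.LOG_T}
_NEEDS_UPPER = {Family.MIRROR_GAMMA, Family.MIRROR_LOG_T}


@dataclass(frozen=True)
class FittedDistribution:
    """One expert's best least-squares fit of one family for one node."""

    expert_id: str
    node_id: str
    params: FamilyParams
    sse: float


def sse(params: FamilyParams, assessment: ProbabilityAssessment) -> float:
    """Sum of squared deviations between elicited and fitted quantiles."""
    p = np.asarray(assessment.probabilities)
    q = np.asarray(assessment.quantiles)
    fitted = np.asarray(quantile(params, p))
    return float(np.sum((q - fitted) ** 2))


def _anchors(assessment: ProbabilityAssessment, family: Family,
             bound_policy: str) -> tuple[float, float] | None:
    """Resolve the (lower, upper) anchor bounds for a family, or None if
    the family is inadmissible under the policy."""
    lo, hi = assessment.support
    q = assessment.quantiles
    if family in _NEEDS_LOWER or family is Family.SHIFTED_SCALED_BETA:
        if not math.isfinite(lo):
            if bound_policy != "elicited":
                return None
            lo = min(q)
    if family in _NEEDS_UPPER or family is Family.SHIFTED_SCALED_BETA:
        if not math.isfinite(hi):
            if bound_policy != "elicited":
                return None
            hi = max(q)
    if family is Family.SHIFTED_SCALED_BETA and not lo < hi:
        return None
    return lo, hi


def _approx_loc_scale(probs, quants, ppf75: float) -> tuple[float, float]:
    """Median and IQR-based location/scale start on an arbitrary point set."""
    med = float(np.interp(0.5, probs, quants))
    q1 = float(np.interp(0.25, probs, quants))
    q3 = float(np.interp(0.75, probs, quants))
    scale = (q3 - q1) / (2.0 * ppf75)
    if not scale > 0:
        spread = max(quants) - min(quants)
        scale = spread / (2.0 * ppf75) if spread > 0 else 1e-3
    return med, scale


def _start(family: Family, assessment: ProbabilityAssessment,
           anchors: tuple[float, float], df: float) -> np.ndarray:
    """Moment-matched starting point in the unconstrained parameter space."""
    probs = np.asarray(assessment.probabilities)
    quants = np.asarray(assessment.quantiles, dtype=float)
    lo, hi = anchors
    z75_n = stats.norm.ppf(0.75)
    z75_t = stats.t.ppf(0.75, df)
    eps = 1e-9
    if family is Family.NORMAL:
        m, s = _approx_loc_scale(probs, quants, z75_n)
        return np.array([m, math.log(s)])
    if family is Family.STUDENT_T:
        m, s = _approx_loc_scale(probs, quants, z75_t)
        return np.array([m, math.log(s)])
    if family in (Family.SHIFTED_GAMMA, Family.MIRROR_GAMMA):
        y = quants - lo if family is Family.SHIFTED_GAMMA else hi - quants
        y = np.maximum(y, eps)
        m, s = _approx_loc_scale(probs if family is Family.SHIFTED_GAMMA else probs,
                                 np.sort(y), z75_n)
        m = max(m, eps)
        shape = max((m / s) ** 2, 1e-3)
        rate = max(m / s**2, 1e-12)
        return np.array([math.log(shape), math.log(rate)])
    if family in (Family.LOGNORMAL, Family.LOG_T, Family.MIRROR_LOG_T):
        if family is Family.MIRROR_LOG_T:
            y = np.sort(np.log(np.maximum(hi - quants, eps)))
        else:
            y = np.log(np.maximum(quants - lo, eps))
        ppf75 = z75_n if family is Family.LOGNORMAL else z75_t
        m, s = _approx_loc_scale(probs, y, ppf75)
        return np.array([m, math.log(max(s, 1e-6))])
    if family is Family.SHIFTED_SCALED_BETA:
        u = np.clip((quants - lo) / (hi - lo), 1e-6, 1.0 - 1e-6)
        m, s = _approx_loc_scale(probs, u, z75_n)
        m = min(max(m, 1e-3), 1.0 - 1e-3)
        v = min(s * s, 0.95 * m * (1.0 - m))
        c = m * (1.0 - m) / v - 1.0 if v > 0 else 4.0
        c = max(c, 1e-2)
        return np.array([math.log(max(m * c, 1e-3)),
                         math.log(max((1.0 - m) * c, 1e-3))])
    raise ValueError(family)  # pragma: no cover


def _build(family: Family, vec: np.ndarray, anchors: tuple[float, float],
           df: float) -> FamilyParams:
    lo, hi = anchors
    if family is Family.NORMAL:
        return FamilyParams(family, {"loc": vec[0], "scale": math.exp(vec[1])})
    if family is Family.STUDENT_T:
        return FamilyParams(family, {"loc": vec[0], "scale": math.exp(vec[1]),
                                     "df": df})
    if family is Family.SHIFTED_GAMMA:
        return FamilyParams(family, {"shape": math.exp(vec[0]),
                                     "rate": math.exp(vec[1])}, support_lower=lo)
    if family is Family.MIRROR_GAMMA:
        return FamilyParams(family, {"shape": math.exp(vec[0]),
                                     "rate": math.exp(vec[1])}, support_upper=hi)
    if family is Family.LOGNORMAL:
        return FamilyParams(family, {"mu": vec[0], "sigma": math.exp(vec[1])},
                            support_lower=lo)
    if family is Family.LOG_T:
        return FamilyParams(family, {"mu": vec[0], "sigma": math.exp(vec[1]),
                                     "df": df}, support_lower=lo)
    if family is Family.MIRROR_LOG_T:
        return FamilyParams(family, {"mu": vec[0], "sigma": math.exp(vec[1]),
                                     "df": df}, support_upper=hi)
    if family is Family.SHIFTED_SCALED_BETA:
        return FamilyParams(family, {"alpha": math.exp(vec[0]),
                                     "beta": math.exp(vec[1])},
                            support_lower=lo, support_upper=hi)
    raise ValueError(family)  # pragma: no cover


def _fast_quantile_fn(family: Family, anchors: tuple[float, float], df: float,
                      probs: np.ndarray):
    """Quantile evaluator specialized to fixed probabilities.

    For location-scale and log families the standard quantiles are
    precomputed, so each optimizer evaluation is pure arithmetic; only the
    gamma and beta shapes still call into scipy per evaluation. Must agree
    with :func:`elicitbn.families.quantile` on the same parameters.
    """
    lo, hi = anchors
    p = np.asarray(probs, dtype=float)
    pm = 1.0 - p

    if family is Family.NORMAL:
        z = stats.norm.ppf(p)
        return lambda v: v[0] + np.exp(v[1]) * z
    if family is Family.STUDENT_T:
        z = stats.t.ppf(p, df)
        return lambda v: v[0] + np.exp(v[1]) * z
    if family is Family.SHIFTED_GAMMA:
        return lambda v: lo + stats.gamma.ppf(p, np.exp(v[0])) / np.exp(v[1])
    if family is Family.MIRROR_GAMMA:
        return lambda v: hi - stats.gamma.ppf(pm, np.exp(v[0])) / np.exp(v[1])
    if family is Family.LOGNORMAL:
        z = stats.norm.ppf(p)
        return lambda v: lo + np.exp(v[0] + np.exp(v[1]) * z)
    if family is Family.LOG_T:
        z = stats.t.ppf(p, df)
        return lambda v: lo + np.exp(v[0] + np.exp(v[1]) * z)
    if family is Family.MIRROR_LOG_T:
        z = stats.t.ppf(pm, df)
        return lambda v: hi - np.exp(v[0] + np.exp(v[1]) * z)
    if family is Family.SHIFTED_SCALED_BETA:
        return lambda v: lo + (hi - lo) * stats.beta.ppf(p, np.exp(v[0]),
                                                         np.exp(v[1]))
    raise ValueError(family)  # pragma: no cover


def fit_family(assessment: ProbabilityAssessment, family: Family,
               df: float = 3.0, seed: int = 0, n_restarts: int = 5,
               bound_policy: str = "elicited") -> FittedDistribution:
    """Least-squares fit of one family to an assessment.

    Deterministic given ``seed``: the optimizer runs from the
    moment-matched start plus ``n_restarts`` jittered copies and keeps the
    lowest SSE. Raises :class:`NoFitError` if the family is inadmissible
    for the assessment's support under ``bound_policy`` and
    :class:`ConvergenceError` if no start converges.
    """
    family = Family(family)
    anchors = _anchors(assessment, family, bound_policy)
    if anchors is None:
        raise NoFitError(
            f"{family.value} is inadmissible for support {assessment.support} "
            f"under bound_policy={bound_policy!r}")
    x0 = _start(family, assessment, anchors, df)
    probs = np.asarray(assessment.probabilities)
    quants = np.asarray(assessment.quantiles, dtype=float)
    qfn = _fast_quantile_fn(family, anchors, df, probs)

    def residuals(vec: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            fitted = qfn(vec)
        fitted = np.where(np.isfinite(fitted), fitted, 1e12)
        return quants - fitted

    def objective(vec: np.ndarray) -> float:
        r = residuals(vec)
        val = float(r @ r)
        return val if math.isfinite(val) else 1e30

    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, 0.25, size=x0.shape)
                     for _ in range(n_restarts)]
    # an exact fit needs no restarts: stop once SSE is at numerical zero
    stop_tol = 1e-13 * (1.0 + float(quants @ quants))
    best_vec, best_val = None, math.inf
    for s in starts:
        try:
            res = optimize.least_squares(residuals, s, method="trf",
                                         xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                         max_nfev=300)
            vec, val = res.x, objective(res.x)
        except Exception:
            continue
        if val < best_val:
            best_vec, best_val = vec, val
        if best_val < stop_tol:
            break
    # Nelder-Mead polish from the best trust-region point guards against
    # flat or kinked residual landscapes near the optimum
    if best_vec is not None and best_val > stop_tol:
        res = optimize.minimize(objective, best_vec, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 250, "maxfev": 250})
        if res.fun < best_val:
            best_vec, best_val = res.x, res.fun
    if best_vec is None or not math.isfinite(best_val) or best_val >= 1e29:
        raise ConvergenceError(
            f"{family.value} fit failed to converge for "
            f"{assessment.expert_id}/{assessment.node_id}")
    params = _build(family, best_vec, anchors, df)
    return FittedDistribution(assessment.expert_id, assessment.node_id,
                              params, best_val)


def fit_best(assessment: ProbabilityAssessment,
             families: tuple[Family, ...] = FAMILY_ORDER,
             df: float = 3.0, seed: int = 0, n_restarts: int = 5,
             bound_policy: str = "elicited",
             rel_tol: float = 1e-8) -> FittedDistribution:
    """Fit every admissible candidate family and return the lowest-SSE fit.

    SSE values within ``rel_tol`` (relative, plus a 1e-12 floor) of the
    minimum count as tied; ties go to the earlier family in the precedence
    order. Inadmissible families are skipped; if all are inadmissible a
    :class:`NoFitError` is raised.
    """
    fits: list[tuple[int, FittedDistribution]] = []
    for idx, fam in enumerate(FAMILY_ORDER):
        if fam not in families:
            continue
        try:
            fits.append((idx, fit_family(assessment, fam, df=df, seed=seed,
                                         n_restarts=n_restarts,
                                         bound_policy=bound_policy)))
        except NoFitError:
            continue
        except ConvergenceError:
            continue
    if not fits:
        raise NoFitError(
            f"no admissible family for {assessment.expert_id}/"
            f"{assessment.node_id} with support {assessment.support}")
    best_sse = min(f.sse for _, f in fits)
    tol = 1e-12 + rel_tol * best_sse
    for _, f in fits:  # precedence order is preserved by construction
        if f.sse <= best_sse + tol:
            return f
    raise AssertionError("unreachable")  # pragma: no cover
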