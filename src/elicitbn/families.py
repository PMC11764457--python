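"""The eight candidate distribution families used in quartile elicitation.

Families follow the SHELF convention: plain location-scale families
(normal, Student-T), families shifted to a finite lower bound
(shifted gamma, lognormal, log-T) and families reflected about a finite
upper bound (mirror gamma, mirror log-T), plus the shifted-scaled beta on a
bounded interval. Mirror constructions give left-skewed shapes on bounded
support: if G has quantile function Q_G, then X = U - G has
Q_X(p) = U - Q_G(1 - p).

Parameter conventions (serialized by name to avoid convention drift):

====================  =============================================
family                theta keys
====================  =============================================
normal                loc, scale
student_t             loc, scale, df
shifted_gamma         shape, rate           (X = L + Gamma(shape, rate))
mirror_gamma          shape, rate           (X = U - Gamma(shape, rate))
lognormal             mu, sigma             (log(X - L) ~ N(mu, sigma))
log_t                 mu, sigma, df         (log(X - L) ~ T(mu, sigma, df))
mirror_log_t          mu, sigma, df         (log(U - X) ~ T(mu, sigma, df))
shifted_scaled_beta   alpha, beta           (X = L + (U - L) Beta(alpha, beta))
====================  =============================================

Log-T-type variables have no finite moments at any df (E[exp(T)] diverges),
so :func:`moments` serves them only through the truncated-numeric fallback.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
from scipy import integrate, stats

from .errors import DomainError, ParameterError, UndefinedMomentError

__all__ = [
    "Family",
    "FAMILY_ORDER",
    "FamilyParams",
    "Moments",
    "quantile",
    "cdf",
    "density",
    "moments",
    "sample",
    "format_family",
    "format_params",
    "parse_params",
    "params_to_json",
    "params_from_json",
]


class Family(str, Enum):
    """Admissible family tags, in the precedence order used for tie-breaking."""

    NORMAL = "normal"
    STUDENT_T = "student_t"
    SHIFTED_GAMMA = "shifted_gamma"
    MIRROR_GAMMA = "mirror_gamma"
    LOGNORMAL = "lognormal"
    LOG_T = "log_t"
    MIRROR_LOG_T = "mirror_log_t"
    SHIFTED_SCALED_BETA = "shifted_scaled_beta"


#: Fixed precedence order (also the tie-break order for best-fit selection).
FAMILY_ORDER: tuple[Family, ...] = tuple(Family)

_DISPLAY = {
    Family.NORMAL: "Normal",
    Family.STUDENT_T: "T",
    Family.SHIFTED_GAMMA: "ShiftedGamma",
    Family.MIRROR_GAMMA: "MirrorGamma",
    Family.LOGNORMAL: "Lognormal",
    Family.LOG_T: "LogT",
    Family.MIRROR_LOG_T: "MirrorlogT",
    Family.SHIFTED_SCALED_BETA: "Beta",
}
_DISPLAY_INVERSE = {v.lower(): k for k, v in _DISPLAY.items()}

_THETA_KEYS = {
    Family.NORMAL: ("loc", "scale"),
    Family.STUDENT_T: ("loc", "scale", "df"),
    Family.SHIFTED_GAMMA: ("shape", "rate"),
    Family.MIRROR_GAMMA: ("shape", "rate"),
    Family.LOGNORMAL: ("mu", "sigma"),
    Family.LOG_T: ("mu", "sigma", "df"),
    Family.MIRROR_LOG_T: ("mu", "sigma", "df"),
    Family.SHIFTED_SCALED_BETA: ("alpha", "beta"),
}

_NEEDS_LOWER = {Family.SHIFTED_GAMMA, Family.LOGNORMAL, Family.LOG_T,
                Family.SHIFTED_SCALED_BETA}
_NEEDS_UPPER = {Family.MIRROR_GAMMA, Family.MIRROR_LOG_T,
                Family.SHIFTED_SCALED_BETA}
_T_TYPE = {Family.STUDENT_T, Family.LOG_T, Family.MIRROR_LOG_T}
_LOG_T_TYPE = {Family.LOG_T, Family.MIRROR_LOG_T}


@dataclass(frozen=True)
class FamilyParams:
    """A fully specified member of one family, with its support bounds.

    ``support_lower`` / ``support_upper`` double as the shift (L) and
    reflection (U) anchors for the shifted / mirror constructions.
    """

    family: Family
    theta: dict[str, float] = field(default_factory=dict)
    support_lower: float = -math.inf
    support_upper: float = math.inf

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        keys = _THETA_KEYS[fam]
        missing = [k for k in keys if k not in self.theta]
        if missing:
            raise ParameterError(f"{fam.value}: missing parameters {missing}")
        extra = [k for k in self.theta if k not in keys]
        if extra:
            raise ParameterError(f"{fam.value}: unknown parameters {extra}")
        th = self.theta
        for key in ("scale", "sigma", "shape", "rate", "alpha", "beta"):
            if key in th and not th[key] > 0:
                raise ParameterError(f"{fam.value}: {key} must be > 0, got {th[key]}")
        if "df" in th and not th["df"] >= 1:
            raise ParameterError(f"{fam.value}: df must be >= 1, got {th['df']}")
        if fam in _NEEDS_LOWER and not math.isfinite(self.support_lower):
            raise ParameterError(f"{fam.value} requires a finite lower support bound")
        if fam in _NEEDS_UPPER and not math.isfinite(self.support_upper):
            raise ParameterError(f"{fam.value} requires a finite upper support bound")
        if fam is Family.SHIFTED_SCALED_BETA and not self.support_lower < self.support_upper:
            raise ParameterError("shifted_scaled_beta requires support_lower < support_upper")

    @property
    def support(self) -> tuple[float, float]:
        lo, hi = -math.inf, math.inf
        if self.family in _NEEDS_LOWER:
            lo = self.support_lower
        if self.family in _NEEDS_UPPER:
            hi = self.support_upper
        return lo, hi

    def with_theta(self, **updates: float) -> "FamilyParams":
        return replace(self, theta={**self.theta, **updates})


def _base_t(th: dict[str, float]):
    return stats.t(df=th["df"], loc=th.get("loc", th.get("mu", 0.0)),
                   scale=th.get("scale", th.get("sigma", 1.0)))


def _frozen(params: FamilyParams):
    """Frozen scipy distribution of the *base* variable, plus a transform tag.

    Returns ``(dist, mode)`` where mode is 'direct' (X = base),
    'mirror' (X = U - base), 'exp' (X = L + exp(base)) or
    'mirror_exp' (X = U - exp(base)).
    """
    fam, th = params.family, params.theta
    if fam is Family.NORMAL:
        return stats.norm(loc=th["loc"], scale=th["scale"]), "direct"
    if fam is Family.STUDENT_T:
        return _base_t(th), "direct"
    if fam is Family.SHIFTED_GAMMA:
        return stats.gamma(a=th["shape"], scale=1.0 / th["rate"],
                           loc=params.support_lower), "direct"
    if fam is Family.MIRROR_GAMMA:
        return stats.gamma(a=th["shape"], scale=1.0 / th["rate"]), "mirror"
    if fam is Family.LOGNORMAL:
        return stats.lognorm(s=th["sigma"], scale=math.exp(th["mu"]),
                             loc=params.support_lower), "direct"
    if fam is Family.LOG_T:
        return _base_t(th), "exp"
    if fam is Family.MIRROR_LOG_T:
        return _base_t(th), "mirror_exp"
    if fam is Family.SHIFTED_SCALED_BETA:
        return stats.beta(a=th["alpha"], b=th["beta"], loc=params.support_lower,
                          scale=params.support_upper - params.support_lower), "direct"
    raise ParameterError(f"unknown family {fam}")  # pragma: no cover


def quantile(params: FamilyParams, p):
    """Quantile function Q(p); strictly increasing on (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise DomainError("probabilities must lie strictly inside (0, 1)")
    dist, mode = _frozen(params)
    U, L = params.support_upper, params.support_lower
    if mode == "direct":
        out = dist.ppf(p)
    elif mode == "mirror":
        out = U - dist.ppf(1.0 - p)
    elif mode == "exp":
        out = L + np.exp(dist.ppf(p))
    else:  # mirror_exp
        out = U - np.exp(dist.ppf(1.0 - p))
    return float(out) if out.ndim == 0 else out


def cdf(params: FamilyParams, x):
    x = np.asarray(x, dtype=float)
    dist, mode = _frozen(params)
    U, L = params.support_upper, params.support_lower
    if mode == "direct":
        out = dist.cdf(x)
    elif mode == "mirror":
        out = dist.sf(U - x)
    elif mode == "exp":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x > L, dist.cdf(np.log(np.maximum(x - L, 1e-300))), 0.0)
    else:  # mirror_exp
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x < U, dist.sf(np.log(np.maximum(U - x, 1e-300))), 1.0)
    return float(out) if out.ndim == 0 else out


def density(params: FamilyParams, x):
    """Probability density; zero outside the declared support."""
    x = np.asarray(x, dtype=float)
    dist, mode = _frozen(params)
    U, L = params.support_upper, params.support_lower
    if mode == "direct":
        out = dist.pdf(x)
    elif mode == "mirror":
        out = dist.pdf(U - x)
    elif mode == "exp":
        y = np.maximum(x - L, 1e-300)
        out = np.where(x > L, dist.pdf(np.log(y)) / y, 0.0)
    else:  # mirror_exp
        y = np.maximum(U - x, 1e-300)
        out = np.where(x < U, dist.pdf(np.log(y)) / y, 0.0)
    lo, hi = params.support
    out = np.where((x < lo) | (x > hi), 0.0, out)
    return float(out) if out.ndim == 0 else out


def sample(params: FamilyParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling; all randomness flows through ``rng``."""
    u = rng.uniform(1e-15, 1.0 - 1e-15, size=n)
    return np.asarray(quantile(params, u))


@dataclass(frozen=True)
class Moments:
    mean: float
    sd: float
    method: str  # 'closed_form' | 'numeric' | 'truncated'


def _truncated_moments(params: FamilyParams,
                       p_range: tuple[float, float] = (0.001, 0.999)) -> Moments:
    lo = quantile(params, p_range[0])
    hi = quantile(params, p_range[1])
    mass = p_range[1] - p_range[0]
    m1, _ = integrate.quad(lambda x: x * density(params, x), lo, hi,
                           epsrel=1e-10, limit=200)
    m2, _ = integrate.quad(lambda x: x * x * density(params, x), lo, hi,
                           epsrel=1e-10, limit=200)
    mean = m1 / mass
    var = m2 / mass - mean * mean
    return Moments(mean, math.sqrt(max(var, 0.0)), "truncated")


def moments(params: FamilyParams, allow_truncated: bool = False) -> Moments:
    """Mean and standard deviation, closed form where they exist.

    T-type families with df <= 2 and log-T-type families (whose moments
    diverge at every df) raise :class:`UndefinedMomentError` unless
    ``allow_truncated`` is set, in which case conditional moments over the
    central 0.001–0.999 quantile range are returned, flagged ``truncated``.
    """
    fam, th = params.family, params.theta
    if fam in _LOG_T_TYPE or (fam is Family.STUDENT_T and th["df"] <= 2):
        if allow_truncated:
            return _truncated_moments(params)
        raise UndefinedMomentError(
            f"{fam.value}: moments are undefined "
            f"(heavy tails); enable the truncated fallback to proceed")
    if fam is Family.NORMAL:
        return Moments(th["loc"], th["scale"], "closed_form")
    if fam is Family.STUDENT_T:
        df = th["df"]
        return Moments(th["loc"], th["scale"] * math.sqrt(df / (df - 2.0)),
                       "closed_form")
    if fam is Family.SHIFTED_GAMMA:
        return Moments(params.support_lower + th["shape"] / th["rate"],
                       math.sqrt(th["shape"]) / th["rate"], "closed_form")
    if fam is Family.MIRROR_GAMMA:
        return Moments(params.support_upper - th["shape"] / th["rate"],
                       math.sqrt(th["shape"]) / th["rate"], "closed_form")
    if fam is Family.LOGNORMAL:
        m = math.exp(th["mu"] + 0.5 * th["sigma"] ** 2)
        sd = m * math.sqrt(math.expm1(th["sigma"] ** 2))
        return Moments(params.support_lower + m, sd, "closed_form")
    if fam is Family.SHIFTED_SCALED_BETA:
        a, b = th["alpha"], th["beta"]
        span = params.support_upper - params.support_lower
        mean01 = a / (a + b)
        var01 = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return Moments(params.support_lower + span * mean01,
                       span * math.sqrt(var01), "closed_form")
    raise ParameterError(f"unknown family {fam}")  # pragma: no cover


# ---------------------------------------------------------------------------
# formatting / serialization

def format_family(family: Family) -> str:
    return _DISPLAY[Family(family)]


def format_params(params: FamilyParams, decimals: int = 2) -> str:
    """Render a params object as a report string, e.g. ``"Beta (7.62, 5.76)"``.

    T-type families print df last as ``df = k``; mirror / shifted families
    append their finite anchor bound so the string is self-contained.
    """
    fam, th = params.family, params.theta
    vals = [th[k] for k in _THETA_KEYS[fam] if k != "df"]
    parts = [f"{v:.{decimals}f}" for v in vals]
    if "df" in th:
        df = th["df"]
        parts.append(f"df = {df:g}")
    if fam in (Family.MIRROR_GAMMA, Family.MIRROR_LOG_T):
        parts.append(f"U = {params.support_upper:g}")
    elif fam in (Family.SHIFTED_GAMMA, Family.LOGNORMAL, Family.LOG_T):
        if params.support_lower != 0.0:
            parts.append(f"L = {params.support_lower:g}")
    elif fam is Family.SHIFTED_SCALED_BETA and (params.support_lower, params.support_upper) != (0.0, 1.0):
        parts.append(f"L = {params.support_lower:g}")
        parts.append(f"U = {params.support_upper:g}")
    return f"{_DISPLAY[fam]} ({', '.join(parts)})"


_STRING_RE = re.compile(r"^\s*([A-Za-z]+)\s*\(([^)]*)\)\s*$")


def parse_params(text: str) -> FamilyParams:
    """Parse a report string produced by :func:`format_params`."""
    m = _STRING_RE.match(text)
    if m is None:
        raise ParameterError(f"cannot parse distribution string: {text!r}")
    name = m.group(1).lower()
    if name not in _DISPLAY_INVERSE:
        raise ParameterError(f"unknown family name in string: {m.group(1)!r}")
    fam = _DISPLAY_INVERSE[name]
    positional: list[float] = []
    named: dict[str, float] = {}
    for token in m.group(2).split(","):
        token = token.strip()
        if not token:
            continue
        if "=" in token:
            key, val = (s.strip() for s in token.split("="))
            named[key.lower()] = float(val)
        else:
            positional.append(float(token))
    keys = [k for k in _THETA_KEYS[fam] if k != "df"]
    if len(positional) != len(keys):
        raise ParameterError(
            f"{fam.value} expects {len(keys)} positional parameters, got {len(positional)}")
    theta = dict(zip(keys, positional))
    if "df" in _THETA_KEYS[fam]:
        if "df" not in named:
            raise ParameterError(f"{fam.value} string must carry 'df = k'")
        theta["df"] = named["df"]
    lower = named.get("l", 0.0 if fam in _NEEDS_LOWER else -math.inf)
    upper = named.get("u", 1.0 if fam is Family.SHIFTED_SCALED_BETA else math.inf)
    return FamilyParams(fam, theta, support_lower=lower, support_upper=upper)


def params_to_json(params: FamilyParams) -> str:
    return json.dumps({
        "family": params.family.value,
        "theta": params.theta,
        "support_lower": params.support_lower,
        "support_upper": params.support_upper,
    })


def params_from_json(text: str | dict) -> FamilyParams:
    obj = json.loads(text) if isinstance(text, str) else text
    return FamilyParams(Family(obj["family"]), dict(obj["theta"]),
                        support_lower=float(obj.get("support_lower", -math.inf)),
                        support_upper=float(obj.get("support_upper", math.inf)))


def admissible(family: Family, support: tuple[float, float]) -> bool:
    """Can ``family`` be anchored to the given (lower, upper) support bounds?"""
    lo, hi = support
    if family in _NEEDS_LOWER and not math.isfinite(lo):
        return False
    if family in _NEEDS_UPPER and not math.isfinite(hi):
        return False
    return True
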