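"""Reading, validating and standardizing expert quartile judgments.

The quartile elicitation method asks each expert for five numbers per
quantity of interest: a plausible lower limit, the lower quartile, the
median, the upper quartile and a plausible upper limit. Judgments arrive as
CSV (columns ``expert_id,node_id,lower,q1,median,q3,upper``) or as JSON
(one object per judgment, same keys). Incomplete responses — any missing
cell, or a degenerate all-identical row — are retained with
``complete = False`` and removed per node by the complete-case filter
before fitting, so each node's expert count n (and the df = n - 1 rule
downstream) reflects only usable judgments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .errors import (ConfigurationError, InsufficientPanelError, SchemaError,
                     ValidationError)

__all__ = [
    "NodeDescriptor",
    "QuartileJudgment",
    "ProbabilityAssessment",
    "read_judgments",
    "write_judgments",
    "read_node_catalog",
    "complete_case_filter",
    "standardize_intervals",
]

_CSV_COLUMNS = ["expert_id", "node_id", "lower", "q1", "median", "q3", "upper"]
_VALUE_FIELDS = ("lower_limit", "q1", "median", "q3", "upper_limit")


@dataclass(frozen=True)
class NodeDescriptor:
    """Catalog entry for one elicited quantity.

    ``kind`` is ``proportion`` (support forced to [0, 1]) or ``continuous``
    (support from the catalog, e.g. [0, inf) for a serum marker).
    """

    node_id: str
    kind: str
    units: str = ""
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("proportion", "continuous"):
            raise ConfigurationError(
                f"node {self.node_id}: kind must be 'proportion' or 'continuous'")
        sup = self.support
        if sup is None:
            sup = (0.0, 1.0) if self.kind == "proportion" else (0.0, math.inf)
        sup = (float(sup[0]), float(sup[1]))
        if self.kind == "proportion" and sup != (0.0, 1.0):
            raise ConfigurationError(
                f"node {self.node_id}: proportion nodes have support [0, 1]")
        if not sup[0] < sup[1]:
            raise ConfigurationError(f"node {self.node_id}: empty support {sup}")
        object.__setattr__(self, "support", sup)


@dataclass(frozen=True)
class QuartileJudgment:
    """One expert's five-point summary for one node; missing cells are None."""

    expert_id: str
    node_id: str
    lower_limit: float | None
    q1: float | None
    median: float | None
    q3: float | None
    upper_limit: float | None
    complete: bool = field(default=True)

    @property
    def values(self) -> tuple[float | None, ...]:
        return (self.lower_limit, self.q1, self.median, self.q3, self.upper_limit)


@dataclass(frozen=True)
class ProbabilityAssessment:
    """(probability, quantile) pairs for one expert and node, ready to fit."""

    expert_id: str
    node_id: str
    points: tuple[tuple[float, float], ...]
    support: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValidationError(
                f"{self.expert_id}/{self.node_id}: assessments need >= 3 points")
        probs = [p for p, _ in self.points]
        quants = [q for _, q in self.points]
        if any(not 0.0 < p < 1.0 for p in probs):
            raise ValidationError(
                f"{self.expert_id}/{self.node_id}: probabilities must lie in (0, 1)")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValidationError(
                f"{self.expert_id}/{self.node_id}: probabilities must strictly increase")
        if any(b < a for a, b in zip(quants, quants[1:])):
            raise ValidationError(
                f"{self.expert_id}/{self.node_id}: quantile values must be non-decreasing")

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(p for p, _ in self.points)

    @property
    def quantiles(self) -> tuple[float, ...]:
        return tuple(q for _, q in self.points)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _classify(expert_id: str, node_id: str, raw: Sequence,
              descriptor: NodeDescriptor) -> QuartileJudgment:
    vals = [None if _is_missing(v) else float(v) for v in raw]
    present = [v for v in vals if v is not None]
    degenerate = len(present) == 5 and len(set(present)) == 1
    complete = len(present) == 5 and not degenerate
    if complete:
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValidationError(
                f"expert {expert_id}, node {node_id}: quartiles are not "
                f"monotone non-decreasing: {present}")
        lo, hi = descriptor.support
        if descriptor.kind == "proportion" and (present[0] < 0.0 or present[-1] > 1.0):
            raise ValidationError(
                f"expert {expert_id}, node {node_id}: proportion values must lie in [0, 1]")
        if present[0] < lo or present[-1] > hi:
            raise ValidationError(
                f"expert {expert_id}, node {node_id}: values outside declared "
                f"support [{lo}, {hi}]")
    return QuartileJudgment(expert_id, node_id, *vals, complete=complete)


def read_judgments(source: str | Path | IO | pd.DataFrame,
                   node_catalog: Iterable[NodeDescriptor]) -> list[QuartileJudgment]:
    """Read a panel of quartile judgments from CSV, JSON or a DataFrame.

    Each row must name a catalog node; monotonicity violations raise a
    :class:`ValidationError` naming the expert and node, and rows with
    missing cells come back with ``complete = False``.
    """
    catalog = {d.node_id: d for d in node_catalog}
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        path = Path(source) if isinstance(source, (str, Path)) else None
        if path is not None and path.suffix.lower() == ".json":
            records = json.loads(path.read_text())
            frame = pd.DataFrame.from_records(records)
            rename = {"lower_limit": "lower", "upper_limit": "upper"}
            frame = frame.rename(columns=rename)
        else:
            frame = pd.read_csv(source)
    missing_cols = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"judgment table is missing columns {missing_cols}")
    if frame.empty:
        raise ValidationError("judgment table contains no rows")
    out: list[QuartileJudgment] = []
    seen: set[tuple[str, str]] = set()
    for _, row in frame.iterrows():
        node_id = str(row["node_id"])
        expert_id = str(row["expert_id"])
        if node_id not in catalog:
            raise SchemaError(f"unknown node_id {node_id!r} (expert {expert_id})")
        key = (expert_id, node_id)
        if key in seen:
            raise SchemaError(f"duplicate judgment for expert {expert_id}, node {node_id}")
        seen.add(key)
        raw = [row[c] for c in ("lower", "q1", "median", "q3", "upper")]
        out.append(_classify(expert_id, node_id, raw, catalog[node_id]))
    return out


def write_judgments(judgments: Iterable[QuartileJudgment],
                    path: str | Path, fmt: str | None = None) -> None:
    """Write judgments as CSV or JSON (inferred from the file suffix)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [{
        "expert_id": j.expert_id, "node_id": j.node_id,
        "lower": j.lower_limit, "q1": j.q1, "median": j.median,
        "q3": j.q3, "upper": j.upper_limit,
    } for j in judgments]
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_node_catalog(source: str | Path | dict) -> list[NodeDescriptor]:
    """Read a node catalog from JSON/YAML ({nodes: [{node_id, kind, ...}]})."""
    if isinstance(source, dict):
        obj = source
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
    entries = obj["nodes"] if isinstance(obj, dict) else obj
    out = []
    for e in entries:
        support = e.get("support")
        if support is not None:
            lo = -math.inf if support[0] is None else float(support[0])
            hi = math.inf if support[1] is None else float(support[1])
            support = (lo, hi)
        out.append(NodeDescriptor(e["node_id"], e["kind"],
                                  units=e.get("units", ""), support=support))
    return out


def complete_case_filter(panel: Iterable[QuartileJudgment],
                         node_id: str) -> list[QuartileJudgment]:
    """Complete-case analysis for one node: keep only complete judgments.

    The retained count n is the per-node expert denominator used for the
    pooled prior's df = n - 1 rule. Never increases panel size; idempotent.
    """
    kept = [j for j in panel if j.node_id == node_id and j.complete]
    if len(kept) < 2:
        raise InsufficientPanelError(
            f"node {node_id}: only {len(kept)} complete judgments; "
            f"at least 2 are required")
    return kept


def standardize_intervals(judgment: QuartileJudgment,
                          descriptor: NodeDescriptor,
                          tail_probability: float = 0.01,
                          include_limits: bool = True) -> ProbabilityAssessment:
    """Attach standardized probabilities to a complete judgment.

    The plausible limits are interpreted as the ``tail_probability`` and
    ``1 - tail_probability`` quantiles (default 0.01 — limits treated as
    near-certain bounds), standardizing away per-expert differences in what
    "highly unlikely to fall outside" meant. With ``include_limits=False``
    only the three quartile points are kept and the limits merely bound the
    support used for fitting.
    """
    if not 0.0 < tail_probability < 0.25:
        raise ConfigurationError(
            f"tail_probability must lie in (0, 0.25), got {tail_probability}")
    if not judgment.complete:
        raise ValidationError(
            f"expert {judgment.expert_id}, node {judgment.node_id}: "
            f"cannot standardize an incomplete judgment")
    t = tail_probability
    if include_limits:
        probs = (t, 0.25, 0.5, 0.75, 1.0 - t)
        quants = judgment.values
    else:
        probs = (0.25, 0.5, 0.75)
        quants = (judgment.q1, judgment.median, judgment.q3)
    return ProbabilityAssessment(
        judgment.expert_id, judgment.node_id,
        tuple(zip(probs, quants)),  # type: ignore[arg-type]
        support=descriptor.support)  # type: ignore[arg-type]
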