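"""Summary tables for a processed panel.

Two report shapes mirror the standard elicitation write-up: a pooled-prior
table (node, pooled mean, pooled SD, best-fit prior string) and a
concordance table (node, prevalent best-fit family as "Family (k/n)").
Nodes whose pooled moments are beta-infeasible are flagged in the pooled
table with the violated bound rather than silently repaired.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .elicitation import NodeDescriptor
from .errors import FeasibilityError, InsufficientPanelError
from .fitting import FittedDistribution
from .pooling import LinearPool, concordance, pooled_moments
from .priors import PriorSpec, format_prior, make_prior

__all__ = ["pooled_prior_table", "concordance_table"]


def pooled_prior_table(pools: Mapping[str, LinearPool],
                       catalog: Iterable[NodeDescriptor],
                       n_experts: Mapping[str, int] | None = None,
                       continuous_strategy: str = "pooled_moment_t",
                       proportion_strategy: str = "beta_moment",
                       seed: int = 0,
                       path: str | Path | None = None) -> pd.DataFrame:
    """Per-node pooled mean, pooled SD and prior string.

    Infeasible or under-populated nodes get a WARN flag and no prior
    string; the run continues for the remaining nodes.
    """
    catalog = {d.node_id: d for d in catalog}
    rows = []
    for node_id, lp in pools.items():
        descriptor = catalog[node_id]
        m = pooled_moments(lp, allow_truncated=True)
        n = (n_experts or {}).get(node_id, len(lp.components))
        row = {"node": node_id, "pooled_mean": m.mean, "pooled_sd": m.sd,
               "n_experts": n, "prior": "", "flag": ""}
        strategy = (proportion_strategy if descriptor.kind == "proportion"
                    else continuous_strategy)
        try:
            prior = make_prior(descriptor, lp, strategy, n_experts=n, seed=seed)
            row["prior"] = format_prior(prior)
        except (FeasibilityError, InsufficientPanelError) as exc:
            row["flag"] = f"WARN: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def concordance_table(fits_by_node: Mapping[str, list[FittedDistribution]],
                      path: str | Path | None = None) -> pd.DataFrame:
    """Per-node prevalent best-fit family census, "Family (k/n)"."""
    rows = []
    for node_id, fits in fits_by_node.items():
        summary = concordance(fits)
        rows.append({"node": node_id,
                     "prevalent_family": summary.prevalent_family.value,
                     "concordance": str(summary)})
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
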