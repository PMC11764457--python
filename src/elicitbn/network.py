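"""Hybrid Bayesian network: typed nodes, ancestral sampling, conditioning.

The network is a DAG mixing continuous and categorical nodes. Root nodes
carry informative priors (beta for proportions of a binary category,
location-scale Student-T or a refit family for continuous quantities);
non-root nodes carry a conditional model class chosen by node type:

* ``cpt`` / ``tabulated`` — (conditional) probability table over parent
  category combinations; ``tabulated`` accepts raw counts and normalizes.
* ``linear``      — Gaussian linear model on numeric parent values.
* ``logistic``    — binary logistic regression on numeric parent values.
* ``multinomial`` — softmax-linear model over >= 2 categories.

Categorical values are represented internally by 0-based category index
(the first listed category is the reference whose proportion the elicited
beta prior describes); sample tables expose category labels. Continuous
root priors are truncated to the node support by inverse-CDF sampling.

Inference is self-contained sampling: ancestral (forward) sampling and
likelihood weighting for evidence conditioning. Categorical root nodes use
prior-predictive semantics by default — each draw samples a proportion
from the beta prior and then the category — with a fixed-proportion mode
(plug in the beta mean) available per network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, ComparisonError, CycleError,
                     DegenerateEvidenceError, SchemaError, ValidationError)
from .families import FamilyParams, cdf as fam_cdf, density as fam_density, \
    params_from_json, params_to_json, quantile as fam_quantile
from .priors import BetaPrior, PriorSpec, StudentTPrior

__all__ = ["NodeSpec", "HybridNetwork", "build_network", "forward_sample",
           "condition", "PosteriorSample", "compare_prior_regimes", "to_dot",
           "network_from_config", "network_to_config", "load_paper_replica"]

_MODEL_CLASSES = ("cpt", "tabulated", "linear", "logistic", "multinomial")


@dataclass(frozen=True)
class NodeSpec:
    """One network node: a prior if root, a conditional model otherwise."""

    node_id: str
    kind: str  # 'continuous' | 'categorical'
    categories: tuple[str, ...] | None = None
    support: tuple[float, float] = (-math.inf, math.inf)
    prior: PriorSpec | None = None
    parents: tuple[str, ...] = ()
    model_class: str | None = None
    model_params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ConfigurationError(
                f"node {self.node_id}: kind must be continuous or categorical")
        if self.kind == "categorical":
            if not self.categories or len(self.categories) < 2:
                raise ConfigurationError(
                    f"node {self.node_id}: categorical nodes need >= 2 categories")
            object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "parents", tuple(self.parents))
        if self.parents:
            if self.model_class not in _MODEL_CLASSES:
                raise ConfigurationError(
                    f"node {self.node_id}: non-root nodes need a model_class "
                    f"in {_MODEL_CLASSES}")
            if (self.kind == "categorical" and len(self.categories) > 2
                    and self.model_class not in ("cpt", "tabulated", "multinomial")):
                raise ConfigurationError(
                    f"node {self.node_id}: >2 categories require cpt, "
                    f"tabulated or multinomial")
            if self.kind == "continuous" and self.model_class != "linear":
                raise ConfigurationError(
                    f"node {self.node_id}: continuous child nodes use the "
                    f"linear model class")
        else:
            if self.prior is None:
                raise ConfigurationError(
                    f"node {self.node_id}: root nodes must carry a prior")

    @property
    def is_root(self) -> bool:
        return not self.parents


@dataclass(frozen=True)
class HybridNetwork:
    """DAG of typed nodes with cached topological order."""

    nodes: dict[str, NodeSpec]
    edges: tuple[tuple[str, str], ...]
    order: tuple[str, ...]
    categorical_mode: str = "prior_predictive"  # or 'fixed_proportion'

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def build_network(specs: Iterable[NodeSpec],
                  edges: Iterable[tuple[str, str]] | None = None,
                  categorical_mode: str = "prior_predictive") -> HybridNetwork:
    """Assemble and validate a network from node specs.

    When ``edges`` is omitted the structure is derived automatically from
    each node's parent list (response ← explanatory names). Cycles and
    dangling parent references are rejected.
    """
    specs = list(specs)
    ids = [s.node_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("node ids must be unique")
    nodes = {s.node_id: s for s in specs}
    derived = [(p, s.node_id) for s in specs for p in s.parents]
    if edges is None:
        edge_list = derived
    else:
        edge_list = [tuple(e) for e in edges]
        if set(edge_list) != set(derived):
            raise ConfigurationError(
                "explicit edges disagree with the nodes' parent lists")
    for p, c in edge_list:
        if p not in nodes:
            raise SchemaError(f"edge references unknown parent node {p!r}")
        if c not in nodes:
            raise SchemaError(f"edge references unknown child node {c!r}")
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from(edge_list)
    try:
        order = tuple(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise CycleError(f"network structure contains a cycle: {path}") from None
    if categorical_mode not in ("prior_predictive", "fixed_proportion"):
        raise ConfigurationError(f"unknown categorical_mode {categorical_mode!r}")
    return HybridNetwork(nodes, tuple(edge_list), order,
                         categorical_mode=categorical_mode)


# ---------------------------------------------------------------------------
# sampling machinery

def _truncated_prior_draw(spec: NodeSpec, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw from a continuous root prior truncated to support."""
    prior = spec.prior
    lo, hi = spec.support
    p = prior.parameters
    if isinstance(p, StudentTPrior):
        dist_cdf = lambda x: stats.t.cdf(x, p.df, loc=p.location, scale=p.scale)
        dist_ppf = lambda q: stats.t.ppf(q, p.df, loc=p.location, scale=p.scale)
    elif isinstance(p, FamilyParams):
        dist_cdf = lambda x: fam_cdf(p, x)
        dist_ppf = lambda q: fam_quantile(p, np.clip(q, 1e-15, 1 - 1e-15))
    else:
        raise ConfigurationError(
            f"node {spec.node_id}: continuous roots need a student_t or "
            f"refit_family prior")
    a = float(dist_cdf(lo)) if math.isfinite(lo) else 0.0
    b = float(dist_cdf(hi)) if math.isfinite(hi) else 1.0
    if not b > a:
        raise ConfigurationError(
            f"node {spec.node_id}: prior has no mass on support [{lo}, {hi}]")
    u = rng.uniform(a + 1e-15, b - 1e-15, size=n)
    return np.asarray(dist_ppf(u), dtype=float)


def _truncated_prior_logpdf(spec: NodeSpec, x: float) -> float:
    prior = spec.prior
    lo, hi = spec.support
    p = prior.parameters
    if isinstance(p, StudentTPrior):
        pdf = stats.t.pdf(x, p.df, loc=p.location, scale=p.scale)
        a = stats.t.cdf(lo, p.df, loc=p.location, scale=p.scale) if math.isfinite(lo) else 0.0
        b = stats.t.cdf(hi, p.df, loc=p.location, scale=p.scale) if math.isfinite(hi) else 1.0
    else:
        pdf = fam_density(p, x)
        a = fam_cdf(p, lo) if math.isfinite(lo) else 0.0
        b = fam_cdf(p, hi) if math.isfinite(hi) else 1.0
    if x < lo or x > hi or pdf <= 0.0:
        return -math.inf
    return math.log(pdf) - math.log(b - a)


def _root_category_probs(spec: NodeSpec, n: int, rng: np.random.Generator,
                         mode: str) -> np.ndarray:
    """Per-draw probability of the first-listed (reference) category."""
    prior = spec.prior
    if not isinstance(prior.parameters, BetaPrior):
        raise ConfigurationError(
            f"node {spec.node_id}: categorical roots need a beta prior")
    bp = prior.parameters
    if mode == "prior_predictive":
        return rng.beta(bp.alpha, bp.beta, size=n)
    return np.full(n, bp.mean)


def _cpt_lookup(spec: NodeSpec, parent_vals: dict[str, np.ndarray],
                network: HybridNetwork) -> np.ndarray:
    """Per-draw probability vectors from a (conditional) probability table.

    ``model_params['table']`` maps a tuple/list of parent category labels to
    a probability (or count) vector over this node's categories; with no
    entry key "*" supplies a default. Tables given as counts ('tabulated')
    are normalized row-wise.
    """
    table = spec.model_params.get("table")
    if table is None:
        raise ConfigurationError(f"node {spec.node_id}: cpt model needs a 'table'")
    # normalize keys to tuples of labels
    norm: dict[tuple[str, ...], np.ndarray] = {}
    default = None
    for key, vec in (table.items() if isinstance(table, dict) else table):
        v = np.asarray(vec, dtype=float)
        if np.any(v < 0) or v.sum() <= 0:
            raise ConfigurationError(
                f"node {spec.node_id}: table rows must be non-negative with mass")
        v = v / v.sum()
        if len(v) != len(spec.categories):
            raise ConfigurationError(
                f"node {spec.node_id}: table row length != number of categories")
        if key in ("*", ("*",)):
            default = v
            continue
        k = (key,) if isinstance(key, str) else tuple(key)
        norm[k] = v
    n = len(next(iter(parent_vals.values())))
    out = np.empty((n, len(spec.categories)))
    parent_labels = []
    for p in spec.parents:
        pspec = network.nodes[p]
        if pspec.kind != "categorical":
            raise ConfigurationError(
                f"node {spec.node_id}: cpt parents must be categorical")
        idx = parent_vals[p].astype(int)
        parent_labels.append(np.asarray(pspec.categories)[idx])
    for i in range(n):
        key = tuple(lbl[i] for lbl in parent_labels)
        row = norm.get(key, default)
        if row is None:
            raise ConfigurationError(
                f"node {spec.node_id}: no table row for parent combination {key}")
        out[i] = row
    return out


def _linear_predictor(spec: NodeSpec, parent_vals: dict[str, np.ndarray],
                      coeffs: Mapping[str, float], intercept: float) -> np.ndarray:
    n = len(next(iter(parent_vals.values())))
    eta = np.full(n, float(intercept))
    for p in spec.parents:
        c = float(coeffs.get(p, 0.0))
        eta = eta + c * parent_vals[p]
    return eta


def _conditional_category_probs(spec: NodeSpec, parent_vals, network) -> np.ndarray:
    """(n, k) matrix of category probabilities for a non-root categorical node."""
    if spec.model_class in ("cpt", "tabulated"):
        return _cpt_lookup(spec, parent_vals, network)
    if spec.model_class == "logistic":
        mp = spec.model_params
        eta = _linear_predictor(spec, parent_vals,
                                mp.get("coefficients", {}),
                                mp.get("intercept", 0.0))
        p1 = 1.0 / (1.0 + np.exp(-eta))  # probability of the first category
        return np.column_stack([p1, 1.0 - p1])
    if spec.model_class == "multinomial":
        mp = spec.model_params
        k = len(spec.categories)
        etas = np.zeros((len(next(iter(parent_vals.values()))), k))
        per_cat = mp.get("coefficients", {})
        intercepts = mp.get("intercepts", {})
        for j, cat in enumerate(spec.categories):
            etas[:, j] = _linear_predictor(spec, parent_vals,
                                           per_cat.get(cat, {}),
                                           intercepts.get(cat, 0.0))
        etas -= etas.max(axis=1, keepdims=True)
        ex = np.exp(etas)
        return ex / ex.sum(axis=1, keepdims=True)
    raise ConfigurationError(
        f"node {spec.node_id}: model class {spec.model_class!r} is not "
        f"categorical")


def _numeric_parent_values(network: HybridNetwork, spec: NodeSpec,
                           values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Numeric representation of parent draws (category index or value)."""
    return {p: values[p] for p in spec.parents}


def _sample_node(network: HybridNetwork, spec: NodeSpec, n: int,
                 rng: np.random.Generator,
                 values: dict[str, np.ndarray]) -> np.ndarray:
    if spec.is_root:
        if spec.kind == "continuous":
            return _truncated_prior_draw(spec, n, rng)
        p1 = _root_category_probs(spec, n, rng, network.categorical_mode)
        return (rng.uniform(size=n) >= p1).astype(float)  # 0 = first category
    parent_vals = _numeric_parent_values(network, spec, values)
    if spec.kind == "continuous":
        mp = spec.model_params
        eta = _linear_predictor(spec, parent_vals, mp.get("coefficients", {}),
                                mp.get("intercept", 0.0))
        sd = float(mp.get("sd", 0.0))
        if not sd > 0.0:
            raise ConfigurationError(
                f"node {spec.node_id}: linear model needs a positive 'sd'")
        draw = eta + rng.normal(0.0, sd, size=n)
        lo, hi = spec.support
        return np.clip(draw, lo, hi)
    probs = _conditional_category_probs(spec, parent_vals, network)
    u = rng.uniform(size=n)
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1).astype(float)


def _check_parameterized(network: HybridNetwork) -> None:
    for spec in network.nodes.values():
        if spec.is_root:
            continue
        if spec.model_class in ("cpt", "tabulated") and "table" not in spec.model_params:
            raise ConfigurationError(f"node {spec.node_id}: unparameterized cpt")
        if spec.model_class == "linear" and "sd" not in spec.model_params:
            raise ConfigurationError(f"node {spec.node_id}: unparameterized linear model")


def _to_frame(network: HybridNetwork, values: dict[str, np.ndarray]) -> pd.DataFrame:
    cols = {}
    for node_id in network.nodes:
        spec = network.nodes[node_id]
        v = values[node_id]
        if spec.kind == "categorical":
            cols[node_id] = np.asarray(spec.categories)[v.astype(int)]
        else:
            cols[node_id] = v
    return pd.DataFrame(cols)


def forward_sample(network: HybridNetwork, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling in topological order; reproducible given seed."""
    _check_parameterized(network)
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for node_id in network.order:
        values[node_id] = _sample_node(network, network.nodes[node_id], n,
                                       rng, values)
    return _to_frame(network, values)


# ---------------------------------------------------------------------------
# evidence conditioning (likelihood weighting)

def _encode_evidence(network: HybridNetwork,
                     evidence: Mapping[str, Any]) -> dict[str, float]:
    enc: dict[str, float] = {}
    for node_id, val in evidence.items():
        if node_id not in network.nodes:
            raise SchemaError(f"evidence names unknown node {node_id!r}")
        spec = network.nodes[node_id]
        if spec.kind == "categorical":
            if val not in spec.categories:
                raise ValidationError(
                    f"evidence {node_id}={val!r} is not one of {spec.categories}")
            enc[node_id] = float(spec.categories.index(val))
        else:
            x = float(val)
            lo, hi = spec.support
            if x < lo or x > hi:
                raise ValidationError(
                    f"evidence {node_id}={x} lies outside support [{lo}, {hi}]")
            enc[node_id] = x
    return enc


@dataclass(frozen=True)
class PosteriorSample:
    """Weighted posterior draws from likelihood weighting."""

    samples: pd.DataFrame
    weights: np.ndarray
    ess: float

    def mean(self, node_id: str) -> float:
        col = self._numeric(node_id)
        return float(np.average(col, weights=self.weights))

    def quantile(self, node_id: str, p: float) -> float:
        col = self._numeric(node_id)
        order = np.argsort(col)
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        return float(np.interp(p, cw, col[order]))

    def category_probs(self, node_id: str) -> dict[str, float]:
        col = self.samples[node_id].to_numpy()
        total = self.weights.sum()
        return {str(c): float(self.weights[col == c].sum() / total)
                for c in pd.unique(col)}

    def _numeric(self, node_id: str) -> np.ndarray:
        col = self.samples[node_id].to_numpy()
        if col.dtype.kind in "fiu":
            return col.astype(float)
        raise ValidationError(
            f"node {node_id} is categorical; use category_probs()")


def condition(network: HybridNetwork, evidence: Mapping[str, Any],
              n: int, seed: int) -> PosteriorSample:
    """Likelihood-weighted posterior sampling under evidence.

    Evidence nodes are clamped to their observed values and each ancestral
    draw is weighted by the product of evidence likelihoods given its
    sampled parents. Raises :class:`DegenerateEvidenceError` when the total
    weight is zero (evidence impossible under the model).
    """
    _check_parameterized(network)
    enc = _encode_evidence(network, evidence)
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    log_w = np.zeros(n)
    for node_id in network.order:
        spec = network.nodes[node_id]
        if node_id not in enc:
            values[node_id] = _sample_node(network, spec, n, rng, values)
            continue
        x = enc[node_id]
        values[node_id] = np.full(n, x)
        if spec.is_root:
            if spec.kind == "continuous":
                log_w += _truncated_prior_logpdf(spec, x)
            else:
                p1 = _root_category_probs(spec, n, rng,
                                          network.categorical_mode)
                prob = p1 if x == 0.0 else 1.0 - p1
                with np.errstate(divide="ignore"):
                    log_w += np.log(prob)
        else:
            parent_vals = _numeric_parent_values(network, spec, values)
            if spec.kind == "continuous":
                mp = spec.model_params
                eta = _linear_predictor(spec, parent_vals,
                                        mp.get("coefficients", {}),
                                        mp.get("intercept", 0.0))
                sd = float(mp["sd"])
                log_w += stats.norm.logpdf(x, loc=eta, scale=sd)
            else:
                probs = _conditional_category_probs(spec, parent_vals, network)
                with np.errstate(divide="ignore"):
                    log_w += np.log(probs[:, int(x)])
    log_w = np.where(np.isfinite(log_w), log_w, -np.inf)
    if np.all(np.isneginf(log_w)):
        raise DegenerateEvidenceError(
            "all likelihood weights are zero under the supplied evidence")
    w = np.exp(log_w - log_w[np.isfinite(log_w)].max())
    w = np.where(np.isfinite(w), w, 0.0)
    total = w.sum()
    if total <= 0.0:
        raise DegenerateEvidenceError(
            "all likelihood weights are zero under the supplied evidence")
    ess = float(total ** 2 / np.sum(w ** 2))
    return PosteriorSample(_to_frame(network, values), w, ess)


# ---------------------------------------------------------------------------
# prior-regime comparison

def compare_prior_regimes(bn_informative: HybridNetwork,
                          bn_flat: HybridNetwork,
                          evidence: Mapping[str, Any] | None,
                          n: int, seed: int) -> pd.DataFrame:
    """Posterior summaries under informative vs flat priors, per node.

    Returns one row per node with weighted posterior means and 5/50/95%
    quantiles under each regime; categorical nodes additionally carry an
    estimated total-variation distance between the two posteriors. The two
    networks must share their node set and edge set.
    """
    if (set(bn_informative.nodes) != set(bn_flat.nodes)
            or set(bn_informative.edges) != set(bn_flat.edges)):
        raise ComparisonError("networks differ in structure; cannot compare")
    evidence = evidence or {}
    post_i = condition(bn_informative, evidence, n, seed)
    post_f = condition(bn_flat, evidence, n, seed + 1)
    rows = []
    for node_id in bn_informative.order:
        spec = bn_informative.nodes[node_id]
        row: dict[str, Any] = {"node_id": node_id, "kind": spec.kind}
        if spec.kind == "continuous":
            for tag, post in (("informative", post_i), ("flat", post_f)):
                row[f"mean_{tag}"] = post.mean(node_id)
                for p in (0.05, 0.5, 0.95):
                    row[f"q{int(p * 100):02d}_{tag}"] = post.quantile(node_id, p)
            row["tv_distance"] = math.nan
        else:
            pi = post_i.category_probs(node_id)
            pf = post_f.category_probs(node_id)
            cats = list(spec.categories)
            row["mean_informative"] = pi.get(cats[0], 0.0)
            row["mean_flat"] = pf.get(cats[0], 0.0)
            row["tv_distance"] = 0.5 * sum(
                abs(pi.get(c, 0.0) - pf.get(c, 0.0)) for c in cats)
        rows.append(row)
    return pd.DataFrame(rows)


def to_dot(network: HybridNetwork) -> str:
    """Deterministic DOT rendering of the DAG (nodes sorted, then edges)."""
    lines = ["digraph elicitbn {"]
    for node_id in sorted(network.nodes):
        spec = network.nodes[node_id]
        shape = "box" if spec.kind == "categorical" else "ellipse"
        lines.append(f'  "{node_id}" [shape={shape}];')
    for p, c in sorted(network.edges):
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# configuration I/O

def _prior_from_config(node_id: str, obj: Mapping[str, Any]) -> PriorSpec:
    kind = obj.get("kind")
    if kind == "beta":
        return PriorSpec(node_id, "beta",
                         BetaPrior(float(obj["alpha"]), float(obj["beta"]),
                                   source=obj.get("source", "moment_match")))
    if kind == "student_t":
        return PriorSpec(node_id, "student_t",
                         StudentTPrior(float(obj["location"]),
                                       float(obj["scale"]), int(obj["df"])))
    if kind == "refit_family":
        return PriorSpec(node_id, "refit_family", params_from_json(obj["params"]))
    raise ConfigurationError(f"node {node_id}: unknown prior kind {kind!r}")


def _prior_to_config(spec: PriorSpec) -> dict[str, Any]:
    p = spec.parameters
    if isinstance(p, BetaPrior):
        return {"kind": "beta", "alpha": p.alpha, "beta": p.beta,
                "source": p.source}
    if isinstance(p, StudentTPrior):
        return {"kind": "student_t", "location": p.location, "scale": p.scale,
                "df": p.df}
    return {"kind": "refit_family", "params": json.loads(params_to_json(p))}


def network_from_config(source: str | Path | Mapping[str, Any]) -> HybridNetwork:
    """Build a network from a YAML/JSON config ({nodes: [...], options: {}})."""
    if isinstance(source, Mapping):
        obj = dict(source)
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
    specs = []
    for e in obj["nodes"]:
        node_id = e["id"]
        support = e.get("support")
        if support is not None:
            lo = -math.inf if support[0] in (None, ".inf", "-inf") else float(support[0])
            hi = math.inf if support[1] in (None, ".inf", "inf") else float(support[1])
            support = (lo, hi)
        else:
            support = (-math.inf, math.inf)
        prior = None
        if "prior" in e:
            prior = _prior_from_config(node_id, e["prior"])
        model = e.get("model", {})
        cpt_table = model.get("table")
        if cpt_table is not None and isinstance(cpt_table, list):
            # YAML cannot key mappings by lists; accept [{given: [...], probs: [...]}]
            model = dict(model)
            model["table"] = {tuple(row["given"]): row["probs"] for row in cpt_table}
        specs.append(NodeSpec(
            node_id=node_id,
            kind=e["kind"],
            categories=tuple(e["categories"]) if "categories" in e else None,
            support=support,
            prior=prior,
            parents=tuple(e.get("parents", ())),
            model_class=model.get("class"),
            model_params={k: v for k, v in model.items() if k != "class"},
        ))
    options = obj.get("options", {})
    return build_network(specs,
                         categorical_mode=options.get("categorical_mode",
                                                      "prior_predictive"))


def network_to_config(network: HybridNetwork) -> dict[str, Any]:
    nodes = []
    for node_id in network.order:
        spec = network.nodes[node_id]
        e: dict[str, Any] = {"id": node_id, "kind": spec.kind}
        if spec.categories:
            e["categories"] = list(spec.categories)
        if any(math.isfinite(b) for b in spec.support):
            e["support"] = [None if not math.isfinite(b) else b
                            for b in spec.support]
        if spec.prior is not None:
            e["prior"] = _prior_to_config(spec.prior)
        if spec.parents:
            e["parents"] = list(spec.parents)
            model = {"class": spec.model_class}
            for k, v in spec.model_params.items():
                if k == "table" and isinstance(v, dict):
                    model["table"] = [{"given": list(key), "probs": list(row)}
                                      for key, row in v.items()]
                else:
                    model[k] = v
            e["model"] = model
        nodes.append(e)
    return {"nodes": nodes,
            "options": {"categorical_mode": network.categorical_mode}}


def load_paper_replica() -> HybridNetwork:
    """The shipped 12-variable pancreatic-cancer network configuration.

    Twelve prognostic variables available at diagnosis, with the published
    pooled informative priors; the edge set is illustrative (the network
    structure is a clinical modelling choice, not derivable from the pooled
    priors) and is documented as such in the config file.
    """
    from importlib import resources
    ref = resources.files("elicitbn.data") / "paper_replica.yaml"
    import yaml
    return network_from_config(yaml.safe_load(ref.read_text()))
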