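"""Discrete Bayesian belief network: CPTs, exact inference, neighborhoods.

A :class:`NetworkModel` holds a learned acyclic structure over discretized
feature nodes (plus the recovery outcome node), one Laplace-smoothed
conditional probability table per node, and the MDL score of the structure.
Arcs encode joint-probability associations, not causal claims.

Inference is exact variable elimination; with any positive smoothing
pseudo-count the joint is strictly positive, but evidence of probability
zero (possible at alpha = 0) raises :class:`DegenerateEvidenceError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .mdl import DEFAULT_LAMBDA, DiscreteDataset, MDLScore, family_mdl, mdl_score
from .structure import DEFAULT_MAX_PARENTS, hill_climb

__all__ = [
    "NetworkModel",
    "ConnectivityStats",
    "DegenerateEvidenceError",
    "fit_cpts",
    "learn_structure",
    "infer_posterior",
    "first_degree_associates",
    "connectivity_stats",
    "arc_influence",
    "to_graphml",
    "to_dot",
    "cpts_to_json",
]

DEFAULT_ALPHA = 1.0


class DegenerateEvidenceError(ValueError):
    """Raised when the supplied evidence has probability zero under the model."""


@dataclass
class NetworkModel:
    """Structure + conditional probability tables over discrete nodes.

    ``cpts[v]`` has shape (q, r): one row per joint parent configuration
    (mixed-radix index over ``parents[v]`` in stored order), one column per
    state of v; every row sums to 1.
    """

    nodes: tuple[str, ...]
    cards: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    n_records: int = 0
    mdl: MDLScore | None = None
    outcome: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.nodes:
            rows = self.cpts[v]
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {v!r} do not sum to 1")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("arc set contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    @property
    def arcs(self) -> list[tuple[str, str]]:
        return [(p, v) for v in self.nodes for p in self.parents[v]]

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for v in self.nodes if node in self.parents[v])

    def parent_config_index(self, node: str, assignment: dict[str, int]) -> int:
        idx = 0
        for p in self.parents[node]:
            idx = idx * self.cards[p] + assignment[p]
        return idx


def fit_cpts(
    parents: dict[str, tuple[str, ...]],
    ds: DiscreteDataset,
    alpha: float = DEFAULT_ALPHA,
    outcome: str | None = None,
    mdl: MDLScore | None = None,
) -> NetworkModel:
    """Laplace-smoothed CPTs from family-wise complete cases.

    Each cell is (count + alpha) / (config_total + alpha * r); a parent
    configuration with no observations becomes the uniform distribution,
    also at alpha = 0 (maximum likelihood elsewhere).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    cpts: dict[str, np.ndarray] = {}
    for v in ds.names:
        ps = tuple(parents.get(v, ()))
        ci = ds.index[v]
        r = ds.cards[ci]
        q = 1
        for p in ps:
            q *= ds.cards[ds.index[p]]
        sub = ds.codes[:, [ci, *[ds.index[p] for p in ps]]]
        sub = sub[(sub >= 0).all(axis=1)]
        pa_idx = np.zeros(sub.shape[0], dtype=np.int64)
        for k, p in enumerate(ps):
            pa_idx = pa_idx * ds.cards[ds.index[p]] + sub[:, 1 + k]
        counts = np.bincount(pa_idx * r + sub[:, 0], minlength=q * r).reshape(q, r).astype(float)
        tot = counts.sum(axis=1, keepdims=True)
        table = np.empty_like(counts)
        empty = tot[:, 0] == 0
        if alpha > 0:
            table = (counts + alpha) / (tot + alpha * r)
        else:
            safe = np.where(tot > 0, tot, 1.0)
            table = counts / safe
        table[empty] = 1.0 / r
        cpts[v] = table
    return NetworkModel(
        nodes=tuple(ds.names),
        cards={v: ds.cards[ds.index[v]] for v in ds.names},
        parents={v: tuple(parents.get(v, ())) for v in ds.names},
        cpts=cpts,
        n_records=ds.n_records,
        mdl=mdl,
        outcome=outcome,
    )


def learn_structure(
    ds: DiscreteDataset,
    structure_weight: float = DEFAULT_LAMBDA,
    max_parents: int = DEFAULT_MAX_PARENTS,
    forbidden=frozenset(),
    required=frozenset(),
    alpha: float = DEFAULT_ALPHA,
    gate: str = "family",
    outcome: str | None = None,
) -> NetworkModel:
    """Greedy MDL hill climbing, then CPT fitting; fully deterministic."""
    parents, score = hill_climb(
        ds,
        structure_weight=structure_weight,
        max_parents=max_parents,
        forbidden=forbidden,
        required=required,
        gate=gate,
    )
    return fit_cpts(parents, ds, alpha=alpha, outcome=outcome, mdl=score)


# -- exact inference -------------------------------------------------------

@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray


def _cpt_factor(model: NetworkModel, node: str) -> _Factor:
    ps = model.parents[node]
    shape = tuple(model.cards[p] for p in ps) + (model.cards[node],)
    return _Factor(ps + (node,), model.cpts[node].reshape(shape))


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    out_vars = tuple(dict.fromkeys(f1.vars + f2.vars))
    axes = {v: i for i, v in enumerate(out_vars)}
    sub1 = [axes[v] for v in f1.vars]
    sub2 = [axes[v] for v in f2.vars]
    out = np.einsum(f1.values, sub1, f2.values, sub2, list(range(len(out_vars))))
    return _Factor(out_vars, out)


def _marginalize(f: _Factor, var: str) -> _Factor:
    i = f.vars.index(var)
    return _Factor(f.vars[:i] + f.vars[i + 1 :], f.values.sum(axis=i))


def _reduce(f: _Factor, var: str, state: int) -> _Factor:
    i = f.vars.index(var)
    return _Factor(f.vars[:i] + f.vars[i + 1 :], np.take(f.values, state, axis=i))


def infer_posterior(
    model: NetworkModel, evidence: dict[str, int], query: str
) -> np.ndarray:
    """Exact posterior over the query node's states by variable elimination.

    Nodes absent from the evidence are marginalized.  The result sums to 1;
    evidence with probability zero raises :class:`DegenerateEvidenceError`.
    """
    if query not in model.cards:
        raise KeyError(f"unknown query variable {query!r}")
    if query in evidence:
        raise ValueError("query variable cannot also be evidence")
    for v, s in evidence.items():
        if v not in model.cards:
            raise KeyError(f"unknown evidence variable {v!r}")
        if not 0 <= s < model.cards[v]:
            raise ValueError(f"evidence state {s} out of range for {v!r}")
    factors = []
    for node in model.nodes:
        f = _cpt_factor(model, node)
        for v in sorted(set(f.vars) & set(evidence)):
            f = _reduce(f, v, evidence[v])
        factors.append(f)
    hidden = [v for v in model.nodes if v != query and v not in evidence]
    # eliminate cheapest variable first (greedy min-size heuristic)
    while hidden:
        costs = []
        for v in hidden:
            touched = [f for f in factors if v in f.vars]
            size = len(set(w for f in touched for w in f.vars))
            costs.append((size, v))
        _, v = min(costs)
        touched = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = touched[0]
        for f in touched[1:]:
            prod = _multiply(prod, f)
        rest.append(_marginalize(prod, v))
        factors = rest
        hidden.remove(v)
    prod = factors[0]
    for f in factors[1:]:
        prod = _multiply(prod, f)
    assert prod.vars == (query,)
    z = float(prod.values.sum())
    if z <= 0.0:
        raise DegenerateEvidenceError("evidence has probability zero under the model")
    return prod.values / z


# -- neighborhood and connectivity queries ---------------------------------

def first_degree_associates(model: NetworkModel, target: str) -> set[str]:
    """Variables adjacent to the target (parents union children), direction-agnostic."""
    if target not in model.cards:
        raise KeyError(f"unknown target {target!r}")
    return set(model.parents[target]) | set(model.children(target))


@dataclass(frozen=True)
class ConnectivityStats:
    n_nodes: int
    n_arcs: int
    degree: dict[str, int]
    outcome_degree: int | None = None


def connectivity_stats(model: NetworkModel, outcome: str | None = None) -> ConnectivityStats:
    outcome = outcome or model.outcome
    degree = {v: 0 for v in model.nodes}
    for p, c in model.arcs:
        degree[p] += 1
        degree[c] += 1
    return ConnectivityStats(
        n_nodes=len(model.nodes),
        n_arcs=len(model.arcs),
        degree=degree,
        outcome_degree=degree[outcome] if outcome is not None else None,
    )


def arc_influence(model: NetworkModel, ds: DiscreteDataset) -> dict[tuple[str, str], float]:
    """Description-length increase if an arc is removed (our influence proxy).

    Larger values mean the arc carries more of the model's fit; this is the
    package's own construction, not a standard MDL quantity.
    """
    out: dict[tuple[str, str], float] = {}
    for p, c in model.arcs:
        full_db, full_mb = family_mdl(ds, c, model.parents[c])
        red = tuple(x for x in model.parents[c] if x != p)
        red_db, red_mb = family_mdl(ds, c, red)
        out[(p, c)] = (red_db + red_mb) - (full_db + full_mb)
    return out


# -- serialization ---------------------------------------------------------

def to_graphml(model: NetworkModel, path: str | Path) -> None:
    g = model.graph()
    for v in g.nodes:
        g.nodes[v]["outcome"] = v == model.outcome
        g.nodes[v]["cardinality"] = model.cards[v]
    nx.write_graphml(g, str(path))


def to_dot(model: NetworkModel, path: str | Path) -> None:
    lines = ["digraph venomnet {"]
    for v in model.nodes:
        shape = "doubleoctagon" if v == model.outcome else "ellipse"
        lines.append(f'  "{v}" [shape={shape}];')
    for p, c in model.arcs:
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def cpts_to_json(model: NetworkModel, path: str | Path) -> None:
    payload = {
        "n_records": model.n_records,
        "outcome": model.outcome,
        "mdl_total": model.mdl.total if model.mdl is not None else None,
        "nodes": {
            v: {
                "cardinality": model.cards[v],
                "parents": list(model.parents[v]),
                "cpt": model.cpts[v].tolist(),
            }
            for v in model.nodes
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def score_structure(model: NetworkModel, ds: DiscreteDataset) -> MDLScore:
    """Recompute the model's MDL score from scratch on a dataset."""
    return mdl_score(model.parents, ds)
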