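"""Independent oracles shared by the tests.

Everything here is deliberately naive (enumeration, direct sampling) so it
cannot share a failure mode with the library's vectorized implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from venomnet.mdl import DiscreteDataset
from venomnet.network import NetworkModel


def sample_from_dag(
    parents: dict[str, tuple[str, ...]],
    cards: dict[str, int],
    n: int,
    rng: np.random.Generator,
    copy_noise: float = 0.05,
) -> DiscreteDataset:
    """Ancestral sampling where each child copies (the rounded mean of) its
    parents with probability 1 - copy_noise, else draws uniformly."""
    names = list(parents)
    order: list[str] = []
    while len(order) < len(names):
        for v in names:
            if v not in order and all(p in order for p in parents[v]):
                order.append(v)
    codes = np.zeros((n, len(names)), dtype=np.int64)
    col = {v: j for j, v in enumerate(names)}
    for v in order:
        ps = parents[v]
        if not ps:
            codes[:, col[v]] = rng.integers(0, cards[v], size=n)
            continue
        target = np.clip(
            np.round(np.mean([codes[:, col[p]] for p in ps], axis=0)), 0, cards[v] - 1
        ).astype(np.int64)
        noise = rng.uniform(size=n) < copy_noise
        codes[:, col[v]] = np.where(noise, rng.integers(0, cards[v], size=n), target)
    return DiscreteDataset(names, codes, [cards[v] for v in names])


def enumerate_joint(model: NetworkModel) -> dict[tuple[int, ...], float]:
    """Brute-force joint table: multiply CPT entries over every assignment."""
    joint: dict[tuple[int, ...], float] = {}
    ranges = [range(model.cards[v]) for v in model.nodes]
    idx = {v: j for j, v in enumerate(model.nodes)}
    for assignment in product(*ranges):
        p = 1.0
        for v in model.nodes:
            pa_idx = 0
            for par in model.parents[v]:
                pa_idx = pa_idx * model.cards[par] + assignment[idx[par]]
            p *= model.cpts[v][pa_idx, assignment[idx[v]]]
        joint[assignment] = p
    return joint


def posterior_by_enumeration(
    model: NetworkModel, evidence: dict[str, int], query: str
) -> np.ndarray:
    """Posterior over the query by summing the brute-force joint."""
    joint = enumerate_joint(model)
    idx = {v: j for j, v in enumerate(model.nodes)}
    out = np.zeros(model.cards[query])
    for assignment, p in joint.items():
        if any(assignment[idx[v]] != s for v, s in evidence.items()):
            continue
        out[assignment[idx[query]]] += p
    return out / out.sum()


def random_network(
    rng: np.random.Generator, n_nodes: int | None = None, max_card: int = 3
) -> NetworkModel:
    """Random DAG (edges on a random node order) with Dirichlet(1) CPTs."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 7))
    names = [f"V{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    cards = {v: int(rng.integers(2, max_card + 1)) for v in names}
    parents: dict[str, tuple[str, ...]] = {v: () for v in names}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < 0.4:
                child = names[order[j]]
                parents[child] = parents[child] + (names[order[i]],)
    cpts = {}
    for v in names:
        q = 1
        for p in parents[v]:
            q *= cards[p]
        cpts[v] = rng.dirichlet(np.ones(cards[v]), size=q)
    return NetworkModel(
        nodes=tuple(names), cards=cards, parents=parents, cpts=cpts, n_records=0
    )


def skeleton_f1(true_arcs, learned_arcs) -> float:
    """F1 of the undirected skeleton (direction-agnostic edge sets)."""
    t = {frozenset(a) for a in true_arcs}
    l = {frozenset(a) for a in learned_arcs}
    if not l and not t:
        return 1.0
    tp = len(t & l)
    if tp == 0:
        return 0.0
    precision = tp / len(l)
    recall = tp / len(t)
    return 2 * precision * recall / (precision + recall)
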