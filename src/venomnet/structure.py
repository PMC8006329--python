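"""Greedy MDL structure search over discrete variables.

Hill climbing starts from the empty graph (plus any required arcs) and
repeatedly applies the best of the operators {add, delete, reverse arc},
subject to acyclicity and a parent-count cap.  A move is accepted only when
it shortens the description length of the families it touches by more than a
fraction ``structure_weight`` (lambda, default 0.01) of their current code
length — a sparsity gate; lambda = 0 recovers plain MDL hill climbing.
``gate="global"`` instead demands an improvement of lambda times the whole
network's current total.

The search is fully deterministic: candidate moves are enumerated in
(operator, node-pair) lexicographic order and ties in improvement go to the
earliest candidate.  ``exhaustive_search`` scores every DAG on a handful of
nodes and serves as the optimality oracle on tiny instances.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .mdl import DEFAULT_LAMBDA, DiscreteDataset, MDLScore, family_mdl

__all__ = ["hill_climb", "exhaustive_search", "enumerate_dags"]

DEFAULT_MAX_PARENTS = 3

Arc = tuple[str, str]


def _pairwise_seed(ds: DiscreteDataset) -> dict[tuple[str, tuple[str, ...]], float]:
    """Family scores for every empty and single-parent family, in one pass.

    Joint pair counts come from one-hot matrix products (a missing cell is an
    all-zero row, so complete-case masking per pair is automatic).
    """
    n, V = ds.codes.shape
    if n == 0 or V == 0:
        return {}
    K = max(ds.cards)
    H = np.zeros((V, n, K))
    rows = np.arange(n)
    for j in range(V):
        obs = ds.codes[:, j] >= 0
        H[j, rows[obs], ds.codes[obs, j]] = 1.0
    # C[p, c, i, j] = number of records with variable p in state i and c in state j
    C = np.einsum("ani,bnj->abij", H, H)
    cfg_tot = C.sum(axis=3, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = C * (np.log2(cfg_tot) - np.log2(C))
    data_pair = np.where(C > 0, terms, 0.0).sum(axis=(2, 3))
    nf = C.sum(axis=(2, 3))
    data_pair = np.where(nf > 0, data_pair * (n / np.maximum(nf, 1)), 0.0)
    cards = np.array(ds.cards, dtype=float)
    with np.errstate(divide="ignore"):
        lognf = np.where(nf > 0, np.log2(np.maximum(nf, 1)), 0.0)
    model_pair = 0.5 * lognf * (cards[None, :] - 1.0) * cards[:, None]
    model_pair = np.where(nf > 0, model_pair, 0.0)
    memo: dict[tuple[str, tuple[str, ...]], float] = {}
    for b, child in enumerate(ds.names):
        col = ds.codes[:, b]
        obs = col[col >= 0]
        n0 = obs.size
        if n0:
            cnt = np.bincount(obs, minlength=ds.cards[b]).astype(float)
            pos = cnt[cnt > 0]
            db = float(np.sum(pos * (np.log2(n0) - np.log2(pos)))) * (n / n0)
            mb = 0.5 * np.log2(n0) * (ds.cards[b] - 1)
            memo[(child, ())] = db + mb
        else:
            memo[(child, ())] = 0.0
        for a, parent in enumerate(ds.names):
            if a == b:
                continue
            memo[(child, (parent,))] = float(data_pair[a, b] + model_pair[a, b])
    return memo


def _descendants(children: dict[str, set[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}

    def visit(v: str) -> set[str]:
        if v in out:
            return out[v]
        acc: set[str] = set()
        out[v] = acc  # DAG: no cycles, safe to publish early
        for c in children.get(v, ()):
            acc.add(c)
            acc |= visit(c)
        return acc

    for v in children:
        visit(v)
    return out


def _has_path(children: dict[str, set[str]], src: str, dst: str, skip: Arc | None) -> bool:
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        for w in children.get(u, ()):
            if skip is not None and (u, w) == skip:
                continue
            if w == dst:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def hill_climb(
    ds: DiscreteDataset,
    structure_weight: float = DEFAULT_LAMBDA,
    max_parents: int = DEFAULT_MAX_PARENTS,
    forbidden: frozenset[Arc] | set[Arc] = frozenset(),
    required: frozenset[Arc] | set[Arc] = frozenset(),
    gate: str = "family",
    max_iterations: int = 500,
) -> tuple[dict[str, tuple[str, ...]], MDLScore]:
    """Greedy MDL search; returns (child -> parents) and the final score."""
    if ds.n_records < 2:
        raise ValueError("structure learning needs at least 2 records")
    if ds.n_variables < 2:
        raise ValueError("structure learning needs at least 2 variables")
    if gate not in ("family", "global"):
        raise ValueError("gate must be 'family' or 'global'")
    names = ds.names
    forbidden = frozenset(forbidden)
    required = frozenset(required)
    parents: dict[str, set[str]] = {v: set() for v in names}
    children: dict[str, set[str]] = {v: set() for v in names}
    for x, y in sorted(required):
        if x not in ds.index or y not in ds.index:
            raise KeyError(f"required arc ({x!r}, {y!r}) names an unknown variable")
        if _has_path(children, y, x, None):
            raise ValueError("required arcs form a cycle")
        parents[y].add(x)
        children[x].add(y)
    for y in names:
        if len(parents[y]) > max_parents:
            raise ValueError(f"required arcs give {y!r} more than {max_parents} parents")

    memo = _pairwise_seed(ds)

    def fscore(child: str, ps: frozenset[str] | set[str]) -> float:
        key = (child, tuple(sorted(ps)))
        if key not in memo:
            db, mb = family_mdl(ds, child, key[1])
            memo[key] = db + mb
        return memo[key]

    fam_now = {v: fscore(v, parents[v]) for v in names}
    total = sum(fam_now.values())
    version = {v: 0 for v in names}  # bumped whenever a family changes
    cache: dict[tuple, tuple] = {}  # (op, x, y) -> (imp, new_fams, ver_y, ver_x)

    for _ in range(max_iterations):
        desc = _descendants(children)
        best = None  # (improvement, op_index, x, y, new_fams)
        # -- adds ----------------------------------------------------------
        for x in names:
            for y in names:
                if x == y or x in parents[y] or (x, y) in forbidden:
                    continue
                if len(parents[y]) >= max_parents:
                    continue
                if x in desc.get(y, ()):  # would close a cycle
                    continue
                ent = cache.get((0, x, y))
                if ent is None or ent[2] != version[y]:
                    new = fscore(y, parents[y] | {x})
                    ent = (fam_now[y] - new, {y: new}, version[y], 0)
                    cache[(0, x, y)] = ent
                imp = ent[0]
                base = fam_now[y] if gate == "family" else total
                if imp > max(structure_weight * base, 1e-9):
                    if best is None or imp > best[0] + 1e-12:
                        best = (imp, 0, x, y, ent[1])
        # -- deletes -------------------------------------------------------
        for y in names:
            for x in sorted(parents[y]):
                if (x, y) in required:
                    continue
                ent = cache.get((1, x, y))
                if ent is None or ent[2] != version[y]:
                    new = fscore(y, parents[y] - {x})
                    ent = (fam_now[y] - new, {y: new}, version[y], 0)
                    cache[(1, x, y)] = ent
                imp = ent[0]
                base = fam_now[y] if gate == "family" else total
                if imp > max(structure_weight * base, 1e-9):
                    if best is None or imp > best[0] + 1e-12:
                        best = (imp, 1, x, y, ent[1])
        # -- reversals -----------------------------------------------------
        for y in names:
            for x in sorted(parents[y]):
                if (x, y) in required or (y, x) in forbidden:
                    continue
                if len(parents[x]) >= max_parents:
                    continue
                if _has_path(children, x, y, (x, y)):  # another x->y path: cycle
                    continue
                ent = cache.get((2, x, y))
                if ent is None or ent[2] != version[y] or ent[3] != version[x]:
                    new_y = fscore(y, parents[y] - {x})
                    new_x = fscore(x, parents[x] | {y})
                    imp = fam_now[y] + fam_now[x] - (new_y + new_x)
                    ent = (imp, {y: new_y, x: new_x}, version[y], version[x])
                    cache[(2, x, y)] = ent
                imp = ent[0]
                base = fam_now[y] + fam_now[x] if gate == "family" else total
                if imp > max(structure_weight * base, 1e-9):
                    if best is None or imp > best[0] + 1e-12:
                        best = (imp, 2, x, y, ent[1])
        if best is None:
            break
        imp, op, x, y, new_fams = best
        if op == 0:
            parents[y].add(x)
            children[x].add(y)
        elif op == 1:
            parents[y].discard(x)
            children[x].discard(y)
        else:
            parents[y].discard(x)
            children[x].discard(y)
            parents[x].add(y)
            children[y].add(x)
        fam_now.update(new_fams)
        for v in new_fams:
            version[v] += 1
        total = sum(fam_now.values())

    structure = {v: tuple(sorted(parents[v])) for v in names}
    data_bits = 0.0
    model_bits = 0.0
    for v in names:
        db, mb = family_mdl(ds, v, structure[v])
        data_bits += db
        model_bits += mb
    score = MDLScore(data_bits, model_bits, structure_weight, dict(fam_now))
    return structure, score


# -- exhaustive oracle for tiny instances ----------------------------------

def enumerate_dags(nodes: list[str]):
    """Yield every DAG over ``nodes`` as a child -> parents mapping.

    Exponential in the number of node pairs; intended for <= 4 nodes (there
    are 25 DAGs on 3 labeled nodes, 543 on 4).
    """
    pairs = list(combinations(range(len(nodes)), 2))
    # each unordered pair is absent, forward, or backward
    def rec(i: int, parents: dict[str, set[str]], children: dict[str, set[str]]):
        if i == len(pairs):
            yield {v: tuple(sorted(parents[v])) for v in nodes}
            return
        a, b = pairs[i]
        u, v = nodes[a], nodes[b]
        yield from rec(i + 1, parents, children)
        for src, dst in ((u, v), (v, u)):
            if not _has_path(children, dst, src, None):
                parents[dst].add(src)
                children[src].add(dst)
                yield from rec(i + 1, parents, children)
                parents[dst].discard(src)
                children[src].discard(dst)

    yield from rec(0, {v: set() for v in nodes}, {v: set() for v in nodes})


def exhaustive_search(
    ds: DiscreteDataset, max_parents: int = DEFAULT_MAX_PARENTS
) -> tuple[dict[str, tuple[str, ...]], float]:
    """Global MDL minimum by scoring every DAG; oracle for <= 4 variables."""
    if ds.n_variables > 4:
        raise ValueError("exhaustive search is limited to 4 variables")
    best_structure = None
    best_total = np.inf
    for structure in enumerate_dags(ds.names):
        if any(len(ps) > max_parents for ps in structure.values()):
            continue
        tot = 0.0
        for v, ps in structure.items():
            db, mb = family_mdl(ds, v, ps)
            tot += db + mb
        if tot < best_total - 1e-12:
            best_total = tot
            best_structure = structure
    assert best_structure is not None
    return best_structure, float(best_total)
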