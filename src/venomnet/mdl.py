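"""Minimum Description Length scoring of discrete directed acyclic graphs.

The score of a candidate structure is the two-part code length, in bits:

* ``data_bits`` — the negative base-2 log-likelihood of the records under
  maximum-likelihood conditional probability tables, accumulated family by
  family over the records that are complete on that family (child plus its
  parents).  Records missing any family member simply drop out of that
  family's term, so missing data never require imputation.
* ``model_bits`` — the parameter-coding penalty (log2 N_f)/2 per free
  parameter, where a node with r bins and parent-configuration count q has
  (r - 1) * q free parameters and N_f is the family's complete-case count.

Lower totals are better.  The score decomposes over families, which is what
makes incremental hill-climbing search cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DiscreteDataset", "MDLScore", "family_mdl", "mdl_score"]

DEFAULT_LAMBDA = 0.01


class DiscreteDataset:
    """Records of integer-coded discrete variables; -1 marks a missing cell."""

    def __init__(self, names: list[str], codes: np.ndarray, cards: list[int]):
        codes = np.asarray(codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape[1] != len(names):
            raise ValueError("codes must be an (n_records, n_variables) array")
        if len(cards) != len(names):
            raise ValueError("one cardinality per variable required")
        for j, k in enumerate(cards):
            if k < 1:
                raise ValueError(f"variable {names[j]!r} has cardinality {k} < 1")
            col = codes[:, j]
            if col.max(initial=-1) >= k:
                raise ValueError(f"variable {names[j]!r} has codes beyond its cardinality")
        self.names = list(names)
        self.codes = codes
        self.cards = [int(k) for k in cards]
        self.index = {v: j for j, v in enumerate(self.names)}

    @property
    def n_records(self) -> int:
        return self.codes.shape[0]

    @property
    def n_variables(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cards: dict[str, int]) -> "DiscreteDataset":
        """Build from a float-coded frame (NaN = missing) and declared cardinalities."""
        names = list(df.columns)
        arr = df.to_numpy(dtype=float)
        codes = np.where(np.isnan(arr), -1, arr).astype(np.int64)
        return cls(names, codes, [cards[v] for v in names])

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.index[name]]


@dataclass
class MDLScore:
    """Decomposed description length of one structure on one dataset."""

    data_bits: float
    model_bits: float
    structure_weight: float = DEFAULT_LAMBDA
    family_scores: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.data_bits + self.model_bits


def family_mdl(
    ds: DiscreteDataset, child: str, parents: tuple[str, ...]
) -> tuple[float, float]:
    """(data_bits, model_bits) for one family, complete cases on the family only.

    The data term is computed on the records complete on the family and
    rescaled by n/nf to the full record count, so families with different
    missingness patterns are compared on a per-record-equal footing (a family
    is otherwise cheaper merely because fewer of its records can be coded).
    With complete data the rescaling is the identity.
    """
    ci = ds.index[child]
    pis = [ds.index[p] for p in parents]
    codes = ds.codes
    child_col = codes[:, ci]
    mask = child_col >= 0
    r = ds.cards[ci]
    q = 1
    # mixed-radix joint index over (child, parents)
    idx = child_col.copy()
    for pi in pis:
        col = codes[:, pi]
        mask = mask & (col >= 0)
        idx = idx * ds.cards[pi] + col
        q *= ds.cards[pi]
    nf = int(mask.sum())
    if nf == 0:
        return 0.0, 0.0
    counts = np.bincount(idx[mask], minlength=r * q).reshape(r, q)
    config_tot = counts.sum(axis=0)  # records per parent configuration
    flat = counts[counts > 0].astype(float)
    tot_rep = np.broadcast_to(config_tot, counts.shape)[counts > 0].astype(float)
    data_bits = float(flat @ np.log2(tot_rep / flat))
    data_bits *= ds.n_records / nf
    model_bits = 0.5 * np.log2(nf) * (r - 1) * q
    return data_bits, model_bits


def _check_acyclic(parents: dict[str, tuple[str, ...]]) -> None:
    state: dict[str, int] = {}

    def visit(v: str) -> None:
        state[v] = 1
        for p in parents.get(v, ()):
            s = state.get(p, 0)
            if s == 1:
                raise ValueError("graph contains a directed cycle")
            if s == 0:
                visit(p)
        state[v] = 2

    for v in parents:
        if state.get(v, 0) == 0:
            visit(v)


def mdl_score(
    parents: dict[str, tuple[str, ...]],
    ds: DiscreteDataset,
    structure_weight: float = DEFAULT_LAMBDA,
) -> MDLScore:
    """Total description length of a DAG (given as child -> parent tuple)."""
    if ds.n_records == 0:
        raise ValueError("cannot score an empty data set")
    for v, ps in parents.items():
        if v not in ds.index:
            raise KeyError(f"variable {v!r} absent from data")
        for p in ps:
            if p not in ds.index:
                raise KeyError(f"variable {p!r} absent from data")
    _check_acyclic(parents)
    data_bits = 0.0
    model_bits = 0.0
    fam: dict[str, float] = {}
    for v in ds.names:
        if v not in parents:
            continue
        db, mb = family_mdl(ds, v, tuple(parents[v]))
        data_bits += db
        model_bits += mb
        fam[v] = db + mb
    return MDLScore(data_bits, model_bits, structure_weight, fam)
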