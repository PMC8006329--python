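"""Raw cohort tables -> model-ready discrete feature tables.

Three steps, in the order the pipeline applies them:

1. natural-log transform of analyte concentrations (with a configurable
   positive floor standing in for values below the limit of quantitation);
2. dropping any variable missing in strictly more than 20% of records;
3. quantile (tertile by default) discretization of continuous variables,
   with cut points fitted on training rows only so held-out patients never
   influence the bins.

Missing values are never imputed; the network engine handles them natively
through family-wise complete-case counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "log_transform_analytes",
    "filter_missing_variables",
    "DiscretizationMap",
    "fit_discretizer",
    "apply_discretizer",
]

MISSING_THRESHOLD = 0.20
DEFAULT_BINS = 3
DEFAULT_LOG_FLOOR = 0.5


def log_transform_analytes(table: CohortTable, floor: float = DEFAULT_LOG_FLOOR) -> CohortTable:
    """Replace each analyte value x by ln(max(x, floor)); missing stays missing.

    Refuses to run twice on the same table (the ``log_transformed`` flag).
    """
    if floor <= 0:
        raise ValueError("log floor must be positive")
    if table.log_transformed:
        raise ValueError("table is already log-transformed; refusing to transform twice")
    out = table.copy()
    for col in table.names(group="analyte"):
        vals = out.df[col].to_numpy(dtype=float)
        neg = np.where(~np.isnan(vals) & (vals < 0))[0]
        if neg.size:
            pid = table.patient_ids[int(neg[0])]
            raise ValueError(
                f"negative analyte value {vals[neg[0]]!r} in column {col!r}, patient {pid!r}"
            )
        with np.errstate(invalid="ignore"):
            out.df[col] = np.log(np.maximum(vals, floor))
    out.log_transformed = True
    out.attrs["log_floor"] = floor
    return out


def filter_missing_variables(
    table: CohortTable, threshold: float = MISSING_THRESHOLD
) -> tuple[CohortTable, list[str]]:
    """Drop feature variables missing in strictly more than ``threshold`` of records.

    A variable missing in exactly ``threshold`` of records is kept (the rule
    is "more than").  Returns the reduced table and the dropped names.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    feats = table.feature_names()
    if feats and len(table.df):
        frac = table.df[feats].isna().to_numpy().mean(axis=0)
        dropped = [c for c, f in zip(feats, frac) if f > threshold]
    else:
        dropped = []
    keep = [c for c in table.df.columns if c not in dropped]
    return table.subset_columns(keep), dropped


@dataclass
class DiscretizationMap:
    """Per-variable interior cut points learned on training rows only.

    ``cuts[v]`` is a strictly increasing list of interior boundaries; a value
    x falls in bin ``searchsorted(cuts, x, side='right')``, so values below
    the training minimum land in the lowest bin and values above the maximum
    in the highest (clamping).  Variables that could not support the
    requested bin count carry an entry in ``flags``.
    """

    cuts: dict[str, list[float]]
    n_bins: int
    fitted_on: list[str]
    flags: dict[str, str] = field(default_factory=dict)

    def bins_for(self, variable: str) -> int:
        return len(self.cuts[variable]) + 1

    def assign(self, variable: str, value: float) -> int:
        return int(np.searchsorted(self.cuts[variable], value, side="right"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cuts": self.cuts,
                    "n_bins": self.n_bins,
                    "fitted_on": self.fitted_on,
                    "flags": self.flags,
                },
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationMap":
        d = json.loads(Path(path).read_text())
        return cls(
            cuts={k: list(map(float, v)) for k, v in d["cuts"].items()},
            n_bins=int(d["n_bins"]),
            fitted_on=list(d["fitted_on"]),
            flags=dict(d["flags"]),
        )


def _continuous_features(table: CohortTable) -> list[str]:
    return [
        c
        for c in table.feature_names()
        if table.columns[c].kind == "continuous"
    ]


def fit_discretizer(
    table: CohortTable,
    training_ids: list[str] | None = None,
    bins: int = DEFAULT_BINS,
    variables: list[str] | None = None,
) -> DiscretizationMap:
    """Quantile cut points from training rows only (linear-interpolation quantiles).

    Duplicate quantiles collapse to fewer bins (flagged ``reduced_bins``); a
    constant variable gets a single bin (``constant``); a variable with no
    observed training value is flagged ``unusable`` and excluded.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    ids = table.patient_ids
    if training_ids is None:
        training_ids = ids
    training_set = set(training_ids)
    mask = np.array([pid in training_set for pid in ids])
    if variables is None:
        variables = _continuous_features(table)
    cuts: dict[str, list[float]] = {}
    flags: dict[str, str] = {}
    for v in variables:
        vals = table.df[v].to_numpy(dtype=float)[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            flags[v] = "unusable"
            continue
        if np.unique(vals).size == 1:
            cuts[v] = []
            flags[v] = "constant"
            continue
        qs = np.quantile(vals, [i / bins for i in range(1, bins)])
        uq = sorted(set(float(q) for q in qs))
        cuts[v] = uq
        if len(uq) < bins - 1:
            flags[v] = "reduced_bins"
    return DiscretizationMap(
        cuts=cuts, n_bins=bins, fitted_on=sorted(training_set), flags=flags
    )


def apply_discretizer(dmap: DiscretizationMap, table: CohortTable) -> pd.DataFrame:
    """Bin every non-missing continuous cell; pass categoricals through.

    Returns a DataFrame of float codes (``NaN`` = missing) over the table's
    feature columns plus any outcome column.  Variables flagged ``unusable``
    are omitted.  Binary/categorical columns keep their original codes.
    """
    cols: dict[str, np.ndarray] = {}
    for c in table.df.columns:
        meta = table.columns[c]
        if meta.group == "id" or meta.group == "psfs":
            continue
        vals = table.df[c].to_numpy()
        if meta.kind == "continuous":
            if c not in dmap.cuts:
                if dmap.flags.get(c) == "unusable":
                    continue
                raise KeyError(f"variable {c!r} not covered by the discretization map")
            fv = vals.astype(float)
            out = np.full(fv.shape, np.nan)
            ok = ~np.isnan(fv)
            out[ok] = np.searchsorted(dmap.cuts[c], fv[ok], side="right")
            cols[c] = out
        else:
            cols[c] = vals.astype(float)
    return pd.DataFrame(cols, index=table.df.index)
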