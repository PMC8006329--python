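"""Patient-by-feature cohort table with typed columns and explicit missingness.

A :class:`CohortTable` wraps a :class:`pandas.DataFrame` (one row per
patient, ``NaN`` = missing) together with per-column metadata: the variable
kind (continuous / binary / categorical), the group it belongs to (analyte,
clinical, PSFS visit, outcome) and the sampling timepoint (pre-antivenom,
post-antivenom or static).  Tables round-trip through a CSV file plus a JSON
metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ColumnInfo", "CohortTable"]

KINDS = ("continuous", "binary", "categorical", "id")
GROUPS = ("id", "analyte", "clinical", "psfs", "outcome")
TIMEPOINT_TAGS = ("pre_antivenom", "post_antivenom", "static")


@dataclass(frozen=True)
class ColumnInfo:
    """Type and provenance of one cohort column."""

    kind: str
    group: str
    timepoint: str = "static"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown column group {self.group!r}")
        if self.timepoint not in TIMEPOINT_TAGS:
            raise ValueError(f"unknown timepoint tag {self.timepoint!r}")


@dataclass
class CohortTable:
    """A patient-by-feature table plus column metadata and transform flags."""

    df: pd.DataFrame
    columns: dict[str, ColumnInfo]
    log_transformed: bool = False
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [c for c in self.df.columns if c not in self.columns]
        if unknown:
            raise ValueError(f"columns without metadata: {unknown}")
        missing = [c for c in self.columns if c not in self.df.columns]
        if missing:
            raise ValueError(f"metadata without columns: {missing}")

    # -- selection helpers -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> list[str]:
        (id_col,) = [c for c, m in self.columns.items() if m.group == "id"]
        return [str(v) for v in self.df[id_col]]

    def names(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        """Column names filtered by group and/or timepoint tag, table order."""
        out = []
        for c in self.df.columns:
            m = self.columns[c]
            if group is not None and m.group != group:
                continue
            if timepoint is not None and m.timepoint != timepoint:
                continue
            out.append(c)
        return out

    def feature_names(self) -> list[str]:
        """Analyte + clinical columns (the modeling candidates)."""
        return [c for c in self.df.columns if self.columns[c].group in ("analyte", "clinical")]

    def missing_fraction(self, column: str) -> float:
        if column not in self.df.columns:
            raise KeyError(column)
        n = len(self.df)
        return float(self.df[column].isna().sum()) / n if n else 0.0

    def copy(self) -> "CohortTable":
        return CohortTable(
            df=self.df.copy(),
            columns=dict(self.columns),
            log_transformed=self.log_transformed,
            attrs=dict(self.attrs),
        )

    def subset_rows(self, index) -> "CohortTable":
        out = self.copy()
        out.df = self.df.loc[index].copy()
        return out

    def subset_columns(self, names: list[str]) -> "CohortTable":
        out = self.copy()
        out.df = self.df[list(names)].copy()
        out.columns = {c: self.columns[c] for c in names}
        return out

    # -- equality (content + missingness mask) -----------------------------
    def content_equal(self, other: "CohortTable") -> bool:
        if list(self.df.columns) != list(other.df.columns):
            return False
        if self.columns != other.columns:
            return False
        a, b = self.df, other.df
        if a.shape != b.shape:
            return False
        for c in a.columns:
            va, vb = a[c].to_numpy(), b[c].to_numpy()
            if self.columns[c].kind == "id" or va.dtype.kind in "OUS":
                if not (pd.Series(va).astype(str) == pd.Series(vb).astype(str)).all():
                    return False
            else:
                va = va.astype(float)
                vb = vb.astype(float)
                if not np.array_equal(np.isnan(va), np.isnan(vb)):
                    return False
                ok = np.isnan(va) | (va == vb)
                if not ok.all():
                    return False
        return True

    # -- I/O ---------------------------------------------------------------
    def write(self, directory: str | Path, stem: str = "cohort") -> Path:
        """Write ``<stem>.csv`` plus ``<stem>.meta.json``; returns the CSV path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{stem}.csv"
        # %.17g round-trips IEEE doubles exactly
        self.df.to_csv(csv_path, index=False, na_rep="", float_format="%.17g")
        meta = {
            "column_order": list(self.df.columns),
            "columns": {c: asdict(m) for c, m in self.columns.items()},
            "log_transformed": self.log_transformed,
            "attrs": self.attrs,
        }
        (directory / f"{stem}.meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        return csv_path

    @classmethod
    def read(cls, directory: str | Path, stem: str = "cohort") -> "CohortTable":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.meta.json").read_text())
        order = meta.get("column_order", list(meta["columns"]))
        columns = {c: ColumnInfo(**meta["columns"][c]) for c in order}
        id_cols = [c for c, m in columns.items() if m.kind == "id"]
        df = pd.read_csv(
            directory / f"{stem}.csv",
            dtype={c: str for c in id_cols},
            keep_default_na=True,
            float_precision="round_trip",
        )
        df = df[list(columns)]
        return cls(
            df=df,
            columns=columns,
            log_transformed=bool(meta.get("log_transformed", False)),
            attrs=dict(meta.get("attrs", {})),
        )
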