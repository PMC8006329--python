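"""Functional-recovery outcome scoring from PSFS trajectories.

The Patient-Specific Functional Scale (PSFS) is a patient-reported 0-10
rating of the ability to perform self-nominated activities, assessed here at
days 0, 7, 14, 21 and 28 after envenoming.  Each patient's trajectory is
summarized by the area under the patient curve (AUPC): the trapezoidal
integral of the score over the 28-day window, normalized by the maximum
possible area 10 x 28 = 280 so that AUPC lies in [0, 1].  The cohort is then
dichotomized at the median AUPC: patients at or above the median are labeled
``good`` recovery, those below ``poor``.

If the day-0 or day-28 visit is unobserved, the nearest observed score is
carried outward as a constant to the boundary; interior missing visits are
bridged by the trapezoid between the neighbouring observed days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "PSFSCurve",
    "RecoveryOutcome",
    "compute_aupc",
    "cohort_aupc_summary",
    "dichotomize_at_median",
    "curves_from_table",
    "outcomes_from_table",
    "read_psfs_long",
    "write_outcomes",
]

DAY_MAX = 28
SCORE_MAX = 10.0
MAX_AREA = SCORE_MAX * DAY_MAX  # 280

GOOD = "good"
POOR = "poor"


@dataclass(frozen=True)
class PSFSCurve:
    """One patient's PSFS trajectory: observed (day, score) pairs."""

    patient_id: str
    days: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError(f"{self.patient_id}: empty PSFS curve")
        if len(self.days) != len(self.scores):
            raise ValueError(f"{self.patient_id}: days/scores length mismatch")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise ValueError(f"{self.patient_id}: days must be strictly increasing")
        if self.days[0] < 0 or self.days[-1] > DAY_MAX:
            raise ValueError(f"{self.patient_id}: days must lie within [0, {DAY_MAX}]")
        for d, s in zip(self.days, self.scores):
            if not (0.0 <= s <= SCORE_MAX):
                raise ValueError(
                    f"{self.patient_id}: score {s} at day {d} outside [0, {SCORE_MAX}]"
                )


@dataclass(frozen=True)
class RecoveryOutcome:
    """AUPC and (optionally) the median-split recovery label for one patient."""

    patient_id: str
    aupc: float
    label: str | None = None
    cohort_median: float | None = None


def compute_aupc(curve: PSFSCurve) -> float:
    """Normalized trapezoidal area under one PSFS trajectory, in [0, 1]."""
    days = list(curve.days)
    scores = list(curve.scores)
    if days[0] > 0:  # carry first observation back to day 0
        days.insert(0, 0)
        scores.insert(0, scores[0])
    if days[-1] < DAY_MAX:  # carry last observation forward to day 28
        days.append(DAY_MAX)
        scores.append(scores[-1])
    area = float(np.trapezoid(scores, days))
    return area / MAX_AREA


def cohort_aupc_summary(outcomes: list[RecoveryOutcome]) -> tuple[float, float, float]:
    """(median, min, max) of the cohort AUPC values; midpoint median for even n."""
    if not outcomes:
        raise ValueError("cannot summarize an empty outcome list")
    vals = np.array([o.aupc for o in outcomes], dtype=float)
    return float(np.median(vals)), float(vals.min()), float(vals.max())


def dichotomize_at_median(outcomes: list[RecoveryOutcome]) -> list[RecoveryOutcome]:
    """Label each patient ``good`` iff AUPC >= cohort median, else ``poor``.

    Requires at least two patients; a median split of fewer is meaningless.
    """
    if len(outcomes) < 2:
        raise ValueError("median dichotomization needs at least 2 patients")
    median, _, _ = cohort_aupc_summary(outcomes)
    return [
        replace(o, label=GOOD if o.aupc >= median else POOR, cohort_median=median)
        for o in outcomes
    ]


def curves_from_table(table: CohortTable) -> list[PSFSCurve]:
    """Extract PSFS curves from a cohort table's ``psfs_day_<d>`` columns."""
    psfs_cols = table.names(group="psfs")
    day_of = {c: int(c.rsplit("_", 1)[1]) for c in psfs_cols}
    curves = []
    for pid, (_, row) in zip(table.patient_ids, table.df.iterrows()):
        obs = [(day_of[c], float(row[c])) for c in psfs_cols if pd.notna(row[c])]
        obs.sort()
        curves.append(
            PSFSCurve(pid, tuple(d for d, _ in obs), tuple(s for _, s in obs))
        )
    return curves


def outcomes_from_table(table: CohortTable) -> list[RecoveryOutcome]:
    """AUPC + median-split labels for every patient in a cohort table."""
    outcomes = [
        RecoveryOutcome(c.patient_id, compute_aupc(c)) for c in curves_from_table(table)
    ]
    return dichotomize_at_median(outcomes)


# -- long-format I/O -------------------------------------------------------

def read_psfs_long(path: str | Path) -> list[PSFSCurve]:
    """Read curves from delimited text with columns patient_id, day, score."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    curves = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        curves.append(
            PSFSCurve(
                str(pid),
                tuple(int(d) for d in grp["day"]),
                tuple(float(s) for s in grp["score"]),
            )
        )
    return curves


def write_outcomes(outcomes: list[RecoveryOutcome], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in outcomes],
            "aupc": [o.aupc for o in outcomes],
            "label": [o.label for o in outcomes],
            "cohort_median": [o.cohort_median for o in outcomes],
        }
    ).to_csv(path, index=False)
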