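"""Seeded synthetic snakebite cohorts with a planted dependency structure.

A scalar latent envenoming severity drives (i) a subset of the 35-plex
cytokine/chemokine panel on the natural-log scale, (ii) several dynamic
clinical variables (white blood cell count, respiratory rate, CO2,
antihistamine use), and (iii) the plateau and speed of the PSFS recovery
trajectory.  The coupling strength is a single dial, ``severity_effect``:
at 0 every feature is independent of recovery (the null regime used for
calibration), while large values make recovery nearly deterministic in the
coupled analytes.

Analytes are generated as ``log value = baseline + sign * severity_effect *
severity + noise`` and exponentiated, giving log-normal concentrations whose
log magnitudes (roughly 1-8, e.g. HGF near 6) match serum panels assayed at
1:50 dilution.  PSFS curves rise logistically from a low day-0 score toward
a severity-dependent plateau, with observation noise, clamped to [0, 10].
Missingness is injected completely at random, per variable.

The generator returns the planted graph, per-patient severities and
median-split labels as :class:`GroundTruth` so structure-recovery and
calibration properties are testable without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .cohort import CohortTable, ColumnInfo
from .outcomes import GOOD, RecoveryOutcome, compute_aupc, curves_from_table, dichotomize_at_median
from .panel import CLINICAL_ALL, CLINICAL_BINARY, CLINICAL_CONTINUOUS, LUMINEX_35, OUTCOME, TIMEPOINTS

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "inject_missingness"]

#: Coupling sign of each severity-responsive analyte: +1 rises with severity,
#: -1 falls.  Directions mirror the good/poor contrasts of the pre-antivenom
#: panel (HGF, EOTAXIN, IL-10, IL-12, CCL2 higher in poor recovery; CXCL10,
#: CCL4, VEGF lower).  Analytes not listed are uncoupled.
DEFAULT_COUPLING_SIGNS: dict[str, int] = {
    "HGF": +1,
    "EOTAXIN": +1,
    "IL10": +1,
    "IL12": +1,
    "CCL2": +1,
    "CXCL10": -1,
    "CCL4": -1,
    "VEGF": -1,
}

#: Baseline log concentrations (natural log of pg/mL-scale values).  Values
#: for severity-coupled analytes sit at representative pre-antivenom serum levels;
#: the rest are plausible mid-panel levels.
DEFAULT_LOG_BASELINES: dict[str, float] = {
    "EGF": 3.7, "EOTAXIN": 4.2, "FGF_BASIC": 1.7, "G_CSF": 3.2, "GM_CSF": 2.1,
    "HGF": 6.2, "IFN_ALPHA": 2.6, "IFN_GAMMA": 1.9, "IL1B": 1.2, "IL1A": 1.5,
    "IL1RA": 4.0, "IL2": 1.8, "IL2R": 3.0, "IL3": 0.9, "IL4": 2.3,
    "IL5": 1.4, "IL6": 2.9, "IL7": 2.2, "IL8": 3.4, "IL9": 2.0,
    "IL10": 1.7, "IL12": 4.3, "IL13": 1.6, "IL15": 1.9, "IL17A": 1.3,
    "IL17F": 1.1, "IL22": 1.5, "CXCL10": 1.6, "CCL2": 5.9, "CXCL9": 4.6,
    "CCL3": 3.8, "CCL4": 4.0, "CCL5": 7.3, "TNF_ALPHA": 1.8, "VEGF": 0.9,
}

#: Default per-variable MCAR rates: a few low-abundance analytes drop out of
#: quantitation in roughly a quarter of records, CO2 panels are occasionally
#: not drawn.  These emulate the anticipated missingness of the assay.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "IL3_pre_antivenom": 0.25,
    "IL3_post_antivenom": 0.25,
    "IL17F_pre_antivenom": 0.25,
    "IL17F_post_antivenom": 0.25,
    "co2": 0.15,
}

ANALYTE_NOISE_SD = 0.75
PSFS_OBS_SD = 0.6
PLATEAU_BASE = 8.8
PLATEAU_SLOPE = 0.9  # multiplied by severity_effect * severity
PLATEAU_NOISE_SD = 0.6
DAY0_MEAN = 2.5
DAY0_SD = 1.0
DAY0_SEVERITY_SLOPE = 0.3
TAU_BASE = 7.0
TAU_SEVERITY_SLOPE = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 24
    seed: int = 0
    analyte_names: tuple[str, ...] = LUMINEX_35
    clinical_names: tuple[str, ...] = CLINICAL_ALL
    timepoints: tuple[str, ...] = TIMEPOINTS
    severity_effect: float = 1.0
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    psfs_days: tuple[int, ...] = (0, 7, 14, 21, 28)
    paired: bool = True
    coupling_signs: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_SIGNS)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if len(self.analyte_names) != 35 or len(set(self.analyte_names)) != 35:
            raise ValueError("analyte_names must be exactly 35 distinct labels")
        if self.severity_effect < 0:
            raise ValueError("severity_effect must be nonnegative")
        if not self.timepoints or any(t not in TIMEPOINTS for t in self.timepoints):
            raise ValueError(f"timepoints must be a nonempty subset of {TIMEPOINTS}")
        if self.psfs_days[0] != 0 or any(
            b <= a for a, b in zip(self.psfs_days, self.psfs_days[1:])
        ):
            raise ValueError("psfs_days must be strictly increasing and start at 0")
        for v, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {v!r} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: graph, severities, and the true labels."""

    planted_dag: frozenset[tuple[str, str]]
    latent_severity: dict[str, float]
    true_labels: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_dag": sorted(map(list, self.planted_dag)),
                    "latent_severity": self.latent_severity,
                    "true_labels": self.true_labels,
                },
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_dag=frozenset(tuple(a) for a in d["planted_dag"]),
            latent_severity={k: float(v) for k, v in d["latent_severity"].items()},
            true_labels=dict(d["true_labels"]),
        )


def _column_schema(config: CohortConfig) -> dict[str, ColumnInfo]:
    cols: dict[str, ColumnInfo] = {"patient_id": ColumnInfo("id", "id")}
    for v in CLINICAL_CONTINUOUS:
        if v in config.clinical_names:
            cols[v] = ColumnInfo("continuous", "clinical")
    for v in CLINICAL_BINARY:
        if v in config.clinical_names:
            cols[v] = ColumnInfo("binary", "clinical")
    for tp in config.timepoints:
        for a in config.analyte_names:
            cols[f"{a}_{tp}"] = ColumnInfo("continuous", "analyte", tp)
    for d in config.psfs_days:
        cols[f"psfs_day_{d}"] = ColumnInfo("continuous", "psfs")
    return cols


def _planted_dag(config: CohortConfig) -> frozenset[tuple[str, str]]:
    arcs: set[tuple[str, str]] = set()
    for a, sign in config.coupling_signs.items():
        if sign == 0 or a not in config.analyte_names:
            continue
        for tp in config.timepoints:
            arcs.add(("latent_severity", f"{a}_{tp}"))
    for v in ("wbc", "resp_rate", "co2", "antihistamines"):
        if v in config.clinical_names:
            arcs.add(("latent_severity", v))
    arcs.add(("latent_severity", OUTCOME))
    return frozenset(arcs)


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate one seeded cohort; identical config + seed is bit-identical."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cols = _column_schema(config)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    data: dict[str, np.ndarray] = {"patient_id": np.array(ids, dtype=object)}
    sev = rng.normal(0.0, 1.0, size=n)
    eff = config.severity_effect

    # clinical variables
    if "age" in config.clinical_names:
        data["age"] = np.round(rng.uniform(25, 80, size=n))
    if "sex" in config.clinical_names:
        data["sex"] = rng.binomial(1, 0.8, size=n).astype(float)  # 1 = female
    if "comorbidity" in config.clinical_names:
        data["comorbidity"] = rng.binomial(1, 0.5, size=n).astype(float)
    if "antihistamines" in config.clinical_names:
        p = 1.0 / (1.0 + np.exp(-(-0.2 + 0.6 * eff * sev)))
        data["antihistamines"] = (rng.uniform(size=n) < p).astype(float)
    if "wbc" in config.clinical_names:
        data["wbc"] = np.clip(7.5 + 1.2 * eff * sev + rng.normal(0, 1.5, n), 2.0, None)
    if "resp_rate" in config.clinical_names:
        data["resp_rate"] = np.clip(16 + 1.5 * eff * sev + rng.normal(0, 2.0, n), 8, 40)
    if "co2" in config.clinical_names:
        data["co2"] = np.clip(25 - 1.2 * eff * sev + rng.normal(0, 2.0, n), 10, 35)

    # analytes, log-normal around a severity-shifted log baseline
    for tp in config.timepoints:
        shift = 0.0 if tp == "pre_antivenom" else rng.normal(0.0, 0.2, size=35)
        for j, a in enumerate(config.analyte_names):
            sign = config.coupling_signs.get(a, 0)
            base = DEFAULT_LOG_BASELINES.get(a, 2.5)
            tp_shift = shift[j] if np.ndim(shift) else 0.0
            logv = base + tp_shift + sign * eff * sev + rng.normal(0, ANALYTE_NOISE_SD, n)
            data[f"{a}_{tp}"] = np.exp(logv)

    # PSFS trajectories: rise from day-0 level toward a severity-dependent plateau
    day0 = np.clip(rng.normal(DAY0_MEAN, DAY0_SD, n) - DAY0_SEVERITY_SLOPE * eff * sev, 0, 10)
    plateau = np.clip(
        PLATEAU_BASE - PLATEAU_SLOPE * eff * sev + rng.normal(0, PLATEAU_NOISE_SD, n), 0, 10
    )
    tau = np.clip(TAU_BASE + TAU_SEVERITY_SLOPE * eff * sev, 3.0, 21.0)
    for d in config.psfs_days:
        mean = day0 + (plateau - day0) * (1.0 - np.exp(-d / tau))
        data[f"psfs_day_{d}"] = np.clip(mean + rng.normal(0, PSFS_OBS_SD, n), 0, 10)

    df = pd.DataFrame({c: data.get(c, np.full(n, np.nan)) for c in cols})
    table = CohortTable(df=df, columns=cols, attrs={"seed": config.seed})

    # unpaired mode: each patient contributes one analyte timepoint only
    if not config.paired and len(config.timepoints) == 2 and n > 0:
        pre_only = rng.uniform(size=n) < 0.5
        for j, only_pre in enumerate(pre_only):
            drop_tp = "post_antivenom" if only_pre else "pre_antivenom"
            for a in config.analyte_names:
                table.df.loc[table.df.index[j], f"{a}_{drop_tp}"] = np.nan

    if config.missing_rates:
        table, _ = inject_missingness(
            table, config.missing_rates, seed=int(rng.integers(0, 2**31 - 1))
        )

    # ground truth labels from the realized trajectories
    if n >= 2:
        outcomes = dichotomize_at_median(
            [RecoveryOutcome(c.patient_id, compute_aupc(c)) for c in curves_from_table(table)]
        )
        labels = {o.patient_id: o.label for o in outcomes}
    elif n == 1:
        labels = {ids[0]: GOOD}
    else:
        labels = {}
    truth = GroundTruth(
        planted_dag=_planted_dag(config),
        latent_severity={pid: float(s) for pid, s in zip(ids, sev)},
        true_labels=labels,
    )
    return table, truth


def inject_missingness(
    table: CohortTable, missing_rates: dict[str, float], seed: int
) -> tuple[CohortTable, dict[str, float]]:
    """Blank each targeted cell independently at its stated rate (MCAR).

    Returns the new table and the realized missing fraction per variable.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    realized: dict[str, float] = {}
    for v in sorted(missing_rates):
        rate = missing_rates[v]
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {v!r} outside [0, 1]")
        if v not in out.df.columns:
            raise KeyError(f"variable {v!r} not in table")
        n = len(out.df)
        if n == 0:
            realized[v] = 0.0
            continue
        mask = rng.uniform(size=n) < rate
        col = out.df[v].to_numpy(dtype=float)
        col[mask] = np.nan
        out.df[v] = col
        realized[v] = float(np.isnan(col).mean())
    return out, realized
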