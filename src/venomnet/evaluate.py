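"""ROC/AUC evaluation of LOO scores, group contrasts, and the run report.

The AUC is the tie-corrected rank-pair statistic: the fraction of
(good, poor) patient pairs in which the good-recovery patient received the
higher score, counting ties as one half.  The ROC curve sweeps each distinct
score once, descending, so tied scores collapse to a single vertex; its
trapezoidal area equals the rank statistic exactly.  An AUC of 0.6 or above
is reported as a good differentiator between good and poor recovery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable
from .outcomes import GOOD, POOR

__all__ = [
    "ROCResult",
    "GroupContrast",
    "roc_auc",
    "auc_from_scores",
    "classify_discriminator",
    "group_contrast_analytes",
    "render_report",
]

logger = logging.getLogger(__name__)

AUC_THRESHOLD = 0.6
GOOD_DIFFERENTIATOR = "good differentiator"
NOT_GOOD_DIFFERENTIATOR = "not a good differentiator"
DEFAULT_CONTRAST_THRESHOLD = 0.25  # natural-log units of median difference


@dataclass(frozen=True)
class ROCResult:
    """ROC vertices, the tie-corrected AUC, and the class counts."""

    points: tuple[tuple[float, float], ...]
    auc: float
    n_good: int
    n_poor: int

    @property
    def trapezoid_area(self) -> float:
        fpr = np.array([p[0] for p in self.points])
        tpr = np.array([p[1] for p in self.points])
        return float(np.trapezoid(tpr, fpr))


def auc_from_scores(scores: np.ndarray, is_good: np.ndarray) -> float:
    """Tie-corrected rank-pair AUC: P(score_good > score_poor) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    is_good = np.asarray(is_good, dtype=bool)
    n_good = int(is_good.sum())
    n_poor = int((~is_good).sum())
    if n_good == 0 or n_poor == 0:
        raise ValueError("AUC needs both good and poor labels")
    ranks = rankdata(scores)  # average ranks handle ties
    u = float(ranks[is_good].sum()) - n_good * (n_good + 1) / 2.0
    return u / (n_good * n_poor)


def roc_auc(scores) -> ROCResult:
    """ROC curve and AUC from LOO scores (objects with .score / .true_label).

    Also accepts an iterable of ``(score, label)`` pairs.
    """
    vals, labels = [], []
    for s in scores:
        if hasattr(s, "score"):
            vals.append(float(s.score))
            labels.append(s.true_label)
        else:
            v, lab = s
            vals.append(float(v))
            labels.append(lab)
    vals = np.array(vals)
    good = np.array([lab == GOOD for lab in labels])
    auc = auc_from_scores(vals, good)
    n_good = int(good.sum())
    n_poor = int((~good).sum())
    points = [(0.0, 0.0)]
    for t in sorted(set(vals), reverse=True):
        sel = vals >= t
        points.append(
            (float((sel & ~good).sum()) / n_poor, float((sel & good).sum()) / n_good)
        )
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return ROCResult(points=tuple(points), auc=float(auc), n_good=n_good, n_poor=n_poor)


def classify_discriminator(auc: float) -> str:
    """Apply the AUC >= 0.6 rule (boundary inclusive)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    return GOOD_DIFFERENTIATOR if auc >= AUC_THRESHOLD else NOT_GOOD_DIFFERENTIATOR


@dataclass(frozen=True)
class GroupContrast:
    """Per-analyte five-number log summaries for the two recovery groups."""

    analyte: str
    good_summary: tuple[float, float, float, float, float] | None
    poor_summary: tuple[float, float, float, float, float] | None
    n_good: int
    n_poor: int
    median_difference: float | None
    flagged: bool


def _five_number(vals: np.ndarray):
    return tuple(float(x) for x in np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0]))


def group_contrast_analytes(
    table: CohortTable,
    labels: dict[str, str],
    threshold: float = DEFAULT_CONTRAST_THRESHOLD,
) -> list[GroupContrast]:
    """Good-vs-poor five-number summaries of every log analyte.

    Flagged when the absolute median difference exceeds ``threshold`` log
    units — an explicit numeric stand-in for a visual boxplot criterion.
    Uses non-missing values only; if a group has no value for an analyte the
    summaries are still emitted but the flag is suppressed.
    """
    if not table.log_transformed:
        raise ValueError("group contrasts are defined on the log-transformed table")
    ids = table.patient_ids
    good_mask = np.array([labels[p] == GOOD for p in ids])
    out = []
    for analyte in table.names(group="analyte"):
        vals = table.df[analyte].to_numpy(dtype=float)
        g = vals[good_mask & ~np.isnan(vals)]
        p = vals[~good_mask & ~np.isnan(vals)]
        if g.size == 0 or p.size == 0:
            logger.warning("analyte %s missing in one whole group; flag suppressed", analyte)
            out.append(
                GroupContrast(
                    analyte,
                    _five_number(g) if g.size else None,
                    _five_number(p) if p.size else None,
                    int(g.size),
                    int(p.size),
                    None,
                    False,
                )
            )
            continue
        diff = float(np.median(p) - np.median(g))
        out.append(
            GroupContrast(
                analyte,
                _five_number(g),
                _five_number(p),
                int(g.size),
                int(p.size),
                diff,
                abs(diff) > threshold,
            )
        )
    return out


# -- the run report --------------------------------------------------------

REQUIRED_ARTIFACTS = (
    "manifest.json",
    "loo_scores.csv",
    "associate_frequency.json",
    "outcomes.csv",
)


def render_report(run_dir: str | Path, out_path: str | Path | None = None) -> str:
    """Render one run directory into a Markdown report (byte-stable).

    Raises with the full list of missing artifacts if the run is incomplete.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"run directory {run_dir} is missing artifacts: {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    scores = pd.read_csv(run_dir / "loo_scores.csv", dtype={"patient_id": str})
    scores["degenerate"] = scores.get("degenerate", pd.Series(dtype=str)).fillna("")
    freq = json.loads((run_dir / "associate_frequency.json").read_text())
    outcomes = pd.read_csv(run_dir / "outcomes.csv", dtype={"patient_id": str})

    roc = roc_auc(list(zip(scores["score"], scores["true_label"])))
    aupc = outcomes["aupc"].to_numpy(dtype=float)
    n_good = int((outcomes["label"] == GOOD).sum())
    n_poor = int((outcomes["label"] == POOR).sum())

    lines = [
        f"# Prognostic network run report — {manifest['timepoint']}",
        "",
        "## Cohort",
        f"- patients: {manifest['n_patients']} ({n_good} good / {n_poor} poor recovery)",
        f"- PSFS AUPC median {np.median(aupc):.3f}, range ({aupc.min():.3f}, {aupc.max():.3f})",
        "",
        "## Missingness filter",
        f"- dropped variables (> {int(100 * 0.20)}% missing): "
        + (", ".join(manifest["dropped_variables"]) or "none"),
        "",
        "## First-degree associates of recovery",
    ]
    for v in sorted(freq, key=lambda v: (-freq[v], v)):
        if freq[v] > 0:
            lines.append(f"- {v}: adjacent in {freq[v]:.2f} of models")
    if not manifest["selected"]:
        lines += ["", "## Final model", "No model: no variable was selected."]
    else:
        lines += ["", "## Final model", f"- variables: {', '.join(manifest['selected'])}"]
        dot = run_dir / "final_model.cpts.json"
        if dot.exists():
            cpts = json.loads(dot.read_text())
            arcs = [
                f"{p} -> {v}"
                for v, nd in sorted(cpts["nodes"].items())
                for p in nd["parents"]
            ]
            degree: dict[str, int] = {v: 0 for v in cpts["nodes"]}
            for v, nd in cpts["nodes"].items():
                for p in nd["parents"]:
                    degree[p] += 1
                    degree[v] += 1
            lines.append(f"- arcs ({len(arcs)}): " + ("; ".join(sorted(arcs)) or "none"))
            lines.append(
                "- connectivity: "
                + ", ".join(f"{v}={degree[v]}" for v in sorted(degree))
            )
    lines += [
        "",
        "## Leave-one-out cross-validation",
        f"- selection mode: {'nested' if manifest['nested_selection'] else 'non-nested'}",
        f"- AUC: {roc.auc:.3f} ({classify_discriminator(roc.auc)})",
        "- ROC points (FPR, TPR): "
        + "; ".join(f"({f:.3f}, {t:.3f})" for f, t in roc.points),
    ]
    deg = scores[scores["degenerate"] != ""]
    if len(deg):
        lines.append(
            "- degenerate folds: "
            + "; ".join(f"{r.patient_id} ({r.degenerate})" for r in deg.itertuples())
        )
    contrasts_path = run_dir / "contrasts.csv"
    if contrasts_path.exists():
        con = pd.read_csv(contrasts_path)
        flagged = con[con["flagged"] == True]  # noqa: E712
        lines += [
            "",
            "## Good-vs-poor log analyte contrasts",
            f"- flagged analytes (|median difference| > {DEFAULT_CONTRAST_THRESHOLD}): "
            + (", ".join(sorted(flagged["analyte"])) or "none"),
        ]
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
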