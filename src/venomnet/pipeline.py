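"""Two-stage prognostic modeling per antivenom timepoint.

Stage one (model selection): learn one network on the full feature table and
one per leave-one-out fold, collect the variables that are first-degree
associates (graph neighbours) of the recovery node in any of those models,
and refit a final network on the selected variables only.

Stage two (evaluation): leave-one-out cross-validation.  For each patient
the entire pipeline — missingness filter, discretization, associate
selection, final model — is retrained without that patient (nested mode, the
default), and the held-out patient is scored by the posterior probability of
good recovery given their discretized non-outcome evidence.  Missing
evidence is marginalized.  The non-nested variant performs selection once on
all patients and only refits the final model per fold.

Discretization cut points are always fitted on the training rows of the fold
at hand, so held-out values never leak into the bins.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, ColumnInfo
from .mdl import DiscreteDataset
from .network import NetworkModel, first_degree_associates, infer_posterior, learn_structure, to_graphml, cpts_to_json
from .outcomes import GOOD, POOR, RecoveryOutcome, outcomes_from_table
from .panel import OUTCOME
from .preprocess import DiscretizationMap, apply_discretizer, filter_missing_variables, fit_discretizer, log_transform_analytes

__all__ = [
    "PipelineConfig",
    "SelectionResult",
    "LooScore",
    "prepare_features",
    "build_full_and_loo_models",
    "select_first_degree_union",
    "fit_final_model",
    "loo_cv_scores",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the modeling pipeline (units: bits for lambda-gated MDL)."""

    structure_weight: float = 0.01
    bins: int = 3
    max_parents: int = 3
    missing_threshold: float = 0.20
    alpha: float = 1.0
    log_floor: float = 0.5
    selection: str = "loo_union"  # or "full_only": associates of the fold model alone
    min_frequency: float = 0.0
    nested: bool = True
    gate: str = "family"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SelectionResult:
    """Output of the model-selection stage for one timepoint."""

    timepoint: str
    full_model: NetworkModel
    loo_models: list[NetworkModel]
    associate_frequency: dict[str, float]
    selected: list[str]
    final_model: NetworkModel | None


@dataclass(frozen=True)
class LooScore:
    """One held-out patient's posterior probability of good recovery."""

    patient_id: str
    score: float
    true_label: str
    evidence_used: tuple[str, ...]
    degenerate: str | None = None


def _label_code(label: str) -> float:
    return 1.0 if label == GOOD else 0.0


def prepare_features(
    cohort: CohortTable,
    timepoint: str,
    config: PipelineConfig = PipelineConfig(),
    outcomes: list[RecoveryOutcome] | None = None,
) -> tuple[CohortTable, list[RecoveryOutcome]]:
    """Select one timepoint's modeling table: clinical + analytes + recovery.

    Analyte columns are renamed to their bare panel labels, log-transformed,
    and the median-split recovery label (good = 1, poor = 0) is appended.
    Outcome labels are computed once from the whole cohort's PSFS curves.
    """
    if outcomes is None:
        outcomes = outcomes_from_table(cohort)
    label_of = {o.patient_id: o.label for o in outcomes}
    table = cohort if cohort.log_transformed else log_transform_analytes(cohort, config.log_floor)

    cols: dict[str, ColumnInfo] = {}
    data: dict[str, object] = {}
    (id_col,) = [c for c, m in table.columns.items() if m.group == "id"]
    cols["patient_id"] = ColumnInfo("id", "id")
    data["patient_id"] = table.df[id_col].to_numpy()
    for c in table.names(group="clinical"):
        cols[c] = table.columns[c]
        data[c] = table.df[c].to_numpy()
    for c in table.names(group="analyte", timepoint=timepoint):
        base = c[: -len(timepoint) - 1] if c.endswith(f"_{timepoint}") else c
        cols[base] = ColumnInfo("continuous", "analyte", timepoint)
        data[base] = table.df[c].to_numpy()
    cols[OUTCOME] = ColumnInfo("binary", "outcome")
    data[OUTCOME] = np.array([_label_code(label_of[p]) for p in table.patient_ids])
    out = CohortTable(
        df=pd.DataFrame(data),
        columns=cols,
        log_transformed=True,
        attrs={"timepoint": timepoint},
    )
    return out, outcomes


def _fold_dataset(
    table: CohortTable, training_ids: list[str], config: PipelineConfig
) -> tuple[DiscreteDataset, DiscretizationMap]:
    """Discretize a table on cut points fitted from the training rows only."""
    dmap = fit_discretizer(table, training_ids=training_ids, bins=config.bins)
    frame = apply_discretizer(dmap, table)
    cards = {}
    for v in frame.columns:
        meta = table.columns[v]
        if meta.kind == "continuous":
            cards[v] = max(dmap.bins_for(v), 1)
        else:
            cards[v] = 2
    tset = set(training_ids)
    keep = [pid in tset for pid in table.patient_ids]
    return DiscreteDataset.from_frame(frame.loc[keep], cards), dmap


def _learn(ds: DiscreteDataset, config: PipelineConfig) -> NetworkModel:
    return learn_structure(
        ds,
        structure_weight=config.structure_weight,
        max_parents=config.max_parents,
        alpha=config.alpha,
        gate=config.gate,
        outcome=OUTCOME,
    )


def build_full_and_loo_models(
    table: CohortTable, config: PipelineConfig = PipelineConfig()
) -> tuple[NetworkModel, list[NetworkModel]]:
    """One structure on all rows plus one per left-out patient.

    The missingness filter runs once on the given table (a shared variable
    space keeps the associate frequencies comparable); discretization is
    refitted inside every training subset.
    """
    ids = table.patient_ids
    if len(ids) < 3:
        raise ValueError("model building needs at least 3 patients")
    table, _ = filter_missing_variables(table, config.missing_threshold)
    ds, _ = _fold_dataset(table, ids, config)
    full = _learn(ds, config)
    loos = []
    for pid in ids:
        train = [p for p in ids if p != pid]
        ds_i, _ = _fold_dataset(table, train, config)
        loos.append(_learn(ds_i, config))
    return full, loos


def select_first_degree_union(
    full_model: NetworkModel,
    loo_models: list[NetworkModel],
    target: str = OUTCOME,
    min_frequency: float = 0.0,
) -> tuple[dict[str, float], list[str]]:
    """Associate frequency over {full} + LOO models, and the selected set.

    A variable is selected when its frequency strictly exceeds
    ``min_frequency``; the default 0 keeps any variable adjacent to the
    target in at least one model (the union rule).
    """
    models = [full_model, *loo_models]
    for m in models:
        if target not in m.cards:
            raise KeyError(f"target {target!r} missing from a model")
    variables = sorted(set(v for m in models for v in m.nodes) - {target})
    freq = {
        v: sum(1 for m in models if v in m.cards and v in first_degree_associates(m, target))
        / len(models)
        for v in variables
    }
    selected = sorted(v for v in variables if freq[v] > min_frequency)
    return freq, selected


def fit_final_model(
    table: CohortTable,
    selected: list[str],
    config: PipelineConfig = PipelineConfig(),
    training_ids: list[str] | None = None,
) -> NetworkModel:
    """Structure + CPTs on the table restricted to selected vars + recovery."""
    if not selected:
        raise ValueError(
            "no variables selected as first-degree associates of recovery; "
            "no final model can be fitted"
        )
    (id_col,) = [c for c, m in table.columns.items() if m.group == "id"]
    keep = [id_col, *[c for c in table.df.columns if c in selected], OUTCOME]
    sub = table.subset_columns(keep)
    ids = training_ids if training_ids is not None else sub.patient_ids
    ds, _ = _fold_dataset(sub, ids, config)
    return _learn(ds, config)


def _select_on(
    table: CohortTable, config: PipelineConfig
) -> tuple[dict[str, float], list[str]]:
    if config.selection == "loo_union":
        full, loos = build_full_and_loo_models(table, config)
        return select_first_degree_union(full, loos, OUTCOME, config.min_frequency)
    if config.selection == "full_only":
        filt, _ = filter_missing_variables(table, config.missing_threshold)
        ds, _ = _fold_dataset(filt, filt.patient_ids, config)
        model = _learn(ds, config)
        assoc = first_degree_associates(model, OUTCOME)
        variables = sorted(set(model.nodes) - {OUTCOME})
        freq = {v: float(v in assoc) for v in variables}
        return freq, sorted(assoc)
    raise ValueError(f"unknown selection mode {config.selection!r}")


def loo_cv_scores(
    table: CohortTable, config: PipelineConfig = PipelineConfig()
) -> list[LooScore]:
    """Leave-one-out posterior scores for every patient in the feature table.

    Nested mode reruns the missingness filter, discretization and associate
    selection inside each training fold; non-nested selects once on all
    patients.  Folds whose training labels collapse to a single class, or
    that select no associate, score 0.5 and are flagged.
    """
    ids = table.patient_ids
    labels = {pid: (GOOD if v == 1.0 else POOR) for pid, v in zip(ids, table.df[OUTCOME])}
    if len(ids) < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 patients")
    if len(set(labels.values())) < 2:
        raise ValueError("both recovery labels must be present")

    shared_selected: list[str] | None = None
    if not config.nested:
        _, shared_selected = _select_on(table, config)

    scores: list[LooScore] = []
    good_idx = 1
    for pid in ids:
        train = [p for p in ids if p != pid]
        train_labels = {labels[p] for p in train}
        if len(train_labels) < 2:
            scores.append(LooScore(pid, 0.5, labels[pid], (), degenerate="single_label_fold"))
            continue
        keep_rows = [p != pid for p in ids]
        train_table = table.subset_rows(np.array(keep_rows))
        train_table, _ = filter_missing_variables(train_table, config.missing_threshold)
        if config.nested:
            _, selected = _select_on(train_table, config)
        else:
            selected = [v for v in shared_selected if v in train_table.df.columns]
        if not selected:
            scores.append(LooScore(pid, 0.5, labels[pid], (), degenerate="empty_selection"))
            continue
        (id_col,) = [c for c, m in train_table.columns.items() if m.group == "id"]
        keep_cols = [id_col, *[c for c in train_table.df.columns if c in selected], OUTCOME]
        sub = train_table.subset_columns(keep_cols)
        dmap = fit_discretizer(sub, training_ids=sub.patient_ids, bins=config.bins)
        frame = apply_discretizer(dmap, sub)
        cards = {
            v: (max(dmap.bins_for(v), 1) if sub.columns[v].kind == "continuous" else 2)
            for v in frame.columns
        }
        ds = DiscreteDataset.from_frame(frame, cards)
        model = _learn(ds, config)
        # discretize the held-out patient's evidence with the fold's cut points
        row = table.df.loc[[p == pid for p in ids]].iloc[0]
        evidence: dict[str, int] = {}
        for v in model.nodes:
            if v == OUTCOME or v not in table.df.columns:
                continue
            val = row[v]
            if pd.isna(val):
                continue
            if table.columns[v].kind == "continuous":
                if v in dmap.cuts:
                    code = dmap.assign(v, float(val))
                else:
                    continue
            else:
                code = int(val)
            if 0 <= code < model.cards[v]:
                evidence[v] = code
        post = infer_posterior(model, evidence, OUTCOME)
        scores.append(
            LooScore(pid, float(post[good_idx]), labels[pid], tuple(sorted(evidence)))
        )
    return scores


# -- run-directory orchestration -------------------------------------------

def training_fold_hash(table: CohortTable, training_ids: list[str]) -> str:
    """Stable hash of the training rows of one fold (for the leakage audit)."""
    tset = set(training_ids)
    keep = [pid in tset for pid in table.patient_ids]
    sub = table.df.loc[keep]
    return hashlib.sha256(sub.to_csv(index=False).encode()).hexdigest()


def run_pipeline(
    cohort: CohortTable,
    timepoint: str,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """End-to-end run for one timepoint; optionally writes run artifacts.

    Returns a dict with the selection result, LOO scores and outcome
    summaries; with ``out_dir`` set, writes GraphML structures, CPT JSON,
    frequencies, scores and a manifest under that directory.
    """
    from .evaluate import roc_auc, classify_discriminator, group_contrast_analytes
    from .outcomes import write_outcomes

    feature_table, outcomes = prepare_features(cohort, timepoint, config)
    label_of = {o.patient_id: o.label for o in outcomes}
    contrasts = group_contrast_analytes(feature_table, label_of)
    filtered, dropped = filter_missing_variables(feature_table, config.missing_threshold)
    full, loos = build_full_and_loo_models(feature_table, config)
    freq, selected = select_first_degree_union(full, loos, OUTCOME, config.min_frequency)
    final = fit_final_model(filtered, selected, config) if selected else None
    selection = SelectionResult(timepoint, full, loos, freq, selected, final)
    scores = loo_cv_scores(feature_table, config)
    roc = roc_auc(scores)
    result = {
        "timepoint": timepoint,
        "outcomes": outcomes,
        "dropped": dropped,
        "selection": selection,
        "scores": scores,
        "roc": roc,
        "verdict": classify_discriminator(roc.auc),
        "contrasts": contrasts,
        "config": config,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        to_graphml(full, out_dir / "full_model.graphml")
        if final is not None:
            to_graphml(final, out_dir / "final_model.graphml")
            cpts_to_json(final, out_dir / "final_model.cpts.json")
        (out_dir / "associate_frequency.json").write_text(
            json.dumps(freq, indent=1, sort_keys=True)
        )
        pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in scores],
                "score": [s.score for s in scores],
                "true_label": [s.true_label for s in scores],
                "degenerate": [s.degenerate or "" for s in scores],
            }
        ).to_csv(out_dir / "loo_scores.csv", index=False)
        write_outcomes(outcomes, out_dir / "outcomes.csv")
        pd.DataFrame(
            {
                "analyte": [c.analyte for c in contrasts],
                "good_median": [
                    c.good_summary[2] if c.good_summary else np.nan for c in contrasts
                ],
                "poor_median": [
                    c.poor_summary[2] if c.poor_summary else np.nan for c in contrasts
                ],
                "median_difference": [
                    np.nan if c.median_difference is None else c.median_difference
                    for c in contrasts
                ],
                "flagged": [c.flagged for c in contrasts],
            }
        ).to_csv(out_dir / "contrasts.csv", index=False)
        manifest = {
            "timepoint": timepoint,
            "n_patients": feature_table.n_patients,
            "dropped_variables": dropped,
            "selected": selected,
            "auc": roc.auc,
            "verdict": result["verdict"],
            "nested_selection": config.nested,
            "artifacts": sorted(p.name for p in out_dir.iterdir()),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
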