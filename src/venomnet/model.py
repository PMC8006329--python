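"""Model/Results interface over the prognostic-network pipeline.

``RecoveryNetworkModel`` is constructed from a cohort table and a timepoint;
``fit()`` runs outcome scoring, preprocessing, full + leave-one-out
structure learning, first-degree-associate selection and final-model
fitting, and returns a :class:`RecoveryNetworkResults` carrying the learned
networks, selection frequencies and diagnostics.  Cross-validated
discrimination is computed by ``results.cross_validate()``; ``summary()``
renders a plain-text table.

    >>> cohort, truth = generate_cohort(CohortConfig(n_patients=24, seed=1))
    >>> res = RecoveryNetworkModel(cohort, timepoint="post_antivenom").fit()
    >>> report = res.cross_validate()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


from .cohort import CohortTable
from .evaluate import GroupContrast, ROCResult, classify_discriminator, group_contrast_analytes, roc_auc
from .network import ConnectivityStats, NetworkModel, connectivity_stats
from .outcomes import RecoveryOutcome, cohort_aupc_summary
from .panel import OUTCOME, TIMEPOINTS
from .pipeline import (
    LooScore,
    PipelineConfig,
    SelectionResult,
    build_full_and_loo_models,
    filter_missing_variables,
    fit_final_model,
    loo_cv_scores,
    prepare_features,
    select_first_degree_union,
)

__all__ = ["RecoveryNetworkModel", "RecoveryNetworkResults", "EvaluationReport"]


@dataclass
class EvaluationReport:
    """Cross-validated discrimination of one fitted timepoint model."""

    scores: list[LooScore]
    roc: ROCResult
    verdict: str
    nested: bool

    @property
    def auc(self) -> float:
        return self.roc.auc


class RecoveryNetworkModel:
    """Prognostic Bayesian-network model of functional recovery.

    Parameters
    ----------
    cohort : CohortTable
        Raw patient-by-feature table (analyte concentrations, clinical
        variables and PSFS visits); see :mod:`venomnet.simulate` for the
        schema.
    timepoint : str
        ``"pre_antivenom"`` or ``"post_antivenom"``; the two timepoints are
        modeled independently.
    config : PipelineConfig
        Structure-search and preprocessing settings.
    """

    def __init__(
        self,
        cohort: CohortTable,
        timepoint: str = "post_antivenom",
        config: PipelineConfig = PipelineConfig(),
    ):
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        self.cohort = cohort
        self.timepoint = timepoint
        self.config = config

    @classmethod
    def from_cohort_dir(
        cls, directory: str | Path, timepoint: str = "post_antivenom", **kwargs
    ) -> "RecoveryNetworkModel":
        return cls(CohortTable.read(directory), timepoint, **kwargs)

    def fit(self) -> "RecoveryNetworkResults":
        feature_table, outcomes = prepare_features(self.cohort, self.timepoint, self.config)
        filtered, dropped = filter_missing_variables(
            feature_table, self.config.missing_threshold
        )
        full, loos = build_full_and_loo_models(feature_table, self.config)
        freq, selected = select_first_degree_union(
            full, loos, OUTCOME, self.config.min_frequency
        )
        final = (
            fit_final_model(filtered, selected, self.config) if selected else None
        )
        selection = SelectionResult(self.timepoint, full, loos, freq, selected, final)
        return RecoveryNetworkResults(
            model=self,
            feature_table=feature_table,
            outcomes=outcomes,
            dropped_variables=dropped,
            selection=selection,
        )


@dataclass
class RecoveryNetworkResults:
    """Fitted networks, selection diagnostics and evaluation methods."""

    model: RecoveryNetworkModel
    feature_table: CohortTable
    outcomes: list[RecoveryOutcome]
    dropped_variables: list[str]
    selection: SelectionResult
    _evaluation: EvaluationReport | None = field(default=None, repr=False)

    # -- convenience accessors --------------------------------------------
    @property
    def full_model(self) -> NetworkModel:
        return self.selection.full_model

    @property
    def final_model(self) -> NetworkModel | None:
        return self.selection.final_model

    @property
    def selected(self) -> list[str]:
        return self.selection.selected

    @property
    def associate_frequency(self) -> dict[str, float]:
        return self.selection.associate_frequency

    def aupc_summary(self) -> tuple[float, float, float]:
        return cohort_aupc_summary(self.outcomes)

    def connectivity(self) -> ConnectivityStats:
        target = self.final_model if self.final_model is not None else self.full_model
        return connectivity_stats(target, OUTCOME)

    def contrasts(self, threshold: float | None = None) -> list[GroupContrast]:
        labels = {o.patient_id: o.label for o in self.outcomes}
        kwargs = {} if threshold is None else {"threshold": threshold}
        return group_contrast_analytes(self.feature_table, labels, **kwargs)

    # -- evaluation --------------------------------------------------------
    def cross_validate(self) -> EvaluationReport:
        """Leave-one-out cross-validated ROC/AUC (cached after first call)."""
        if self._evaluation is None:
            scores = loo_cv_scores(self.feature_table, self.model.config)
            roc = roc_auc(scores)
            self._evaluation = EvaluationReport(
                scores=scores,
                roc=roc,
                verdict=classify_discriminator(roc.auc),
                nested=self.model.config.nested,
            )
        return self._evaluation

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        med, lo, hi = self.aupc_summary()
        n_good = sum(1 for o in self.outcomes if o.label == "good")
        n_poor = len(self.outcomes) - n_good
        conn = self.connectivity()
        lines = [
            "Prognostic recovery network".center(58),
            "=" * 58,
            f"Timepoint:            {self.model.timepoint}",
            f"Patients:             {len(self.outcomes)} ({n_good} good / {n_poor} poor)",
            f"PSFS AUPC:            median {med:.3f}, range ({lo:.3f}, {hi:.3f})",
            f"Dropped (missing):    {', '.join(self.dropped_variables) or 'none'}",
            f"Selected associates:  {', '.join(self.selected) or 'none'}",
            f"Network:              {conn.n_nodes} nodes, {conn.n_arcs} arcs, "
            f"outcome degree {conn.outcome_degree}",
        ]
        if self._evaluation is not None:
            ev = self._evaluation
            lines.append(
                f"LOO-CV AUC:           {ev.auc:.3f} ({ev.verdict}; "
                f"{'nested' if ev.nested else 'non-nested'} selection)"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_roc(self, ax=None):
        """ROC curve of the LOO scores; requires cross_validate() first."""
        import matplotlib.pyplot as plt

        ev = self.cross_validate()
        if ax is None:
            _, ax = plt.subplots()
        fpr = [p[0] for p in ev.roc.points]
        tpr = [p[1] for p in ev.roc.points]
        ax.plot(fpr, tpr, marker="o", label=f"AUC = {ev.auc:.2f}")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey")
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"LOO-CV ROC — {self.model.timepoint}")
        ax.legend()
        return ax

    def plot_network(self, ax=None, which: str = "final"):
        """Draw the final (or full) network with the outcome node highlighted."""
        import matplotlib.pyplot as plt
        import networkx as nx

        model = self.final_model if which == "final" and self.final_model else self.full_model
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        g = model.graph()
        pos = nx.circular_layout(g)
        colors = ["#d62728" if v == OUTCOME else "#1f77b4" for v in g.nodes]
        nx.draw_networkx(g, pos, ax=ax, node_color=colors, font_size=7, node_size=450)
        ax.set_axis_off()
        return ax
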