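"""Synthetic cohort generator: schema, determinism, planted-signal behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from venomnet.cohort import CohortTable
from venomnet.outcomes import compute_aupc, curves_from_table
from venomnet.panel import LUMINEX_35, panel_names
from venomnet.simulate import CohortConfig, generate_cohort, inject_missingness


class TestPanel:
    def test_thirty_five_distinct_labels(self):
        names = panel_names()
        assert len(names) == 35
        assert len(set(names)) == 35

    def test_contains_key_analytes(self):
        names = panel_names()
        for a in ("EGF", "HGF", "CCL5", "VEGF", "CXCL10", "TNF_ALPHA"):
            assert a in names


class TestGenerateCohort:
    def test_empty_cohort_has_full_schema(self):
        table, truth = generate_cohort(CohortConfig(n_patients=0, seed=0))
        assert table.n_patients == 0
        for a in LUMINEX_35:
            assert f"{a}_pre_antivenom" in table.df.columns
            assert f"{a}_post_antivenom" in table.df.columns
        assert truth.latent_severity == {} and truth.true_labels == {}

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_patients=12, seed=7)
        t1, _ = generate_cohort(cfg)
        t2, _ = generate_cohort(cfg)
        p1 = t1.write(tmp_path / "a")
        p2 = t2.write(tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        t1, _ = generate_cohort(CohortConfig(n_patients=12, seed=1))
        t2, _ = generate_cohort(CohortConfig(n_patients=12, seed=2))
        assert not t1.content_equal(t2)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=-1)

    def test_analytes_positive_lognormal_scale(self, default_cohort):
        table, _ = default_cohort
        for a in ("HGF", "CCL5", "VEGF"):
            vals = table.df[f"{a}_pre_antivenom"].dropna()
            assert (vals > 0).all()
        # log medians should sit near the configured baselines (HGF ~ 6.2)
        assert 5.0 < np.log(table.df["HGF_pre_antivenom"].dropna()).median() < 7.5

    def test_clinical_ranges(self, default_cohort):
        table, _ = default_cohort
        assert table.df["age"].between(25, 80).all()
        assert set(table.df["sex"].dropna().unique()) <= {0.0, 1.0}
        assert (table.df["wbc"].dropna() > 0).all()

    def test_severity_aupc_correlation_strongly_negative(self):
        cfg = CohortConfig(
            n_patients=2000, seed=5, severity_effect=3.0, missing_rates={}
        )
        table, truth = generate_cohort(cfg)
        aupc = np.array([compute_aupc(c) for c in curves_from_table(table)])
        sev = np.array([truth.latent_severity[p] for p in table.patient_ids])
        r = np.corrcoef(sev, aupc)[0, 1]
        assert r < -0.5

    def test_severity_quartile_monotonicity(self):
        cfg = CohortConfig(n_patients=1000, seed=11, missing_rates={})
        table, truth = generate_cohort(cfg)
        aupc = np.array([compute_aupc(c) for c in curves_from_table(table)])
        sev = np.array([truth.latent_severity[p] for p in table.patient_ids])
        hi = aupc[sev >= np.quantile(sev, 0.75)].mean()
        lo = aupc[sev <= np.quantile(sev, 0.25)].mean()
        assert hi < lo

    def test_planted_dag_is_acyclic_and_stored(self, default_cohort):
        import networkx as nx

        _, truth = default_cohort
        g = nx.DiGraph(list(truth.planted_dag))
        assert nx.is_directed_acyclic_graph(g)
        assert ("latent_severity", "recovery") in truth.planted_dag

    def test_null_generator_analytes_independent_of_label(self):
        """With severity_effect = 0, discretized analytes carry no label signal."""
        cfg = CohortConfig(n_patients=1500, seed=3, severity_effect=0.0, missing_rates={})
        table, truth = generate_cohort(cfg)
        labels = np.array(
            [truth.true_labels[p] == "good" for p in table.patient_ids]
        )
        nonsig = 0
        analytes = [f"{a}_pre_antivenom" for a in LUMINEX_35]
        for col in analytes:
            vals = table.df[col].to_numpy()
            bins = np.digitize(vals, np.quantile(vals, [1 / 3, 2 / 3]))
            ct = pd.crosstab(bins, labels)
            _, p, _, _ = chi2_contingency(ct)
            nonsig += p > 0.01
        assert nonsig >= 0.9 * len(analytes)

    def test_roundtrip_preserves_content_and_missingness(self, tmp_path, default_cohort):
        table, _ = default_cohort
        table.write(tmp_path)
        back = CohortTable.read(tmp_path)
        assert table.content_equal(back)

    def test_unpaired_mode_blanks_one_timepoint_per_patient(self):
        cfg = CohortConfig(n_patients=30, seed=2, paired=False, missing_rates={})
        table, _ = generate_cohort(cfg)
        pre = table.df[[f"{a}_pre_antivenom" for a in LUMINEX_35]].isna().all(axis=1)
        post = table.df[[f"{a}_post_antivenom" for a in LUMINEX_35]].isna().all(axis=1)
        assert (pre ^ post).all()


class TestInjectMissingness:
    def test_rate_zero_unchanged(self, default_cohort):
        table, _ = default_cohort
        out, realized = inject_missingness(table, {"wbc": 0.0}, seed=1)
        assert table.content_equal(out)
        assert realized["wbc"] == 0.0

    def test_rate_one_blanks_column(self, default_cohort):
        table, _ = default_cohort
        out, realized = inject_missingness(table, {"EGF_pre_antivenom": 1.0}, seed=1)
        assert out.df["EGF_pre_antivenom"].isna().all()
        assert realized["EGF_pre_antivenom"] == 1.0

    def test_realized_rate_concentrates(self):
        cfg = CohortConfig(n_patients=1000, seed=9, missing_rates={})
        table, _ = generate_cohort(cfg)
        _, realized = inject_missingness(table, {"wbc": 0.3}, seed=4)
        assert 0.25 <= realized["wbc"] <= 0.35

    def test_unknown_variable_rejected(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(KeyError):
            inject_missingness(table, {"not_a_column": 0.1}, seed=0)

    def test_bad_rate_rejected(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(ValueError):
            inject_missingness(table, {"wbc": 1.5}, seed=0)
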