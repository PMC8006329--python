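"""Log transform, missingness filter, and leakage-free discretization."""

import numpy as np
import pandas as pd
import pytest

from venomnet.cohort import CohortTable, ColumnInfo
from venomnet.preprocess import (
    apply_discretizer,
    filter_missing_variables,
    fit_discretizer,
    log_transform_analytes,
)


def make_table(values: dict[str, list], kinds: dict[str, str] | None = None) -> CohortTable:
    n = len(next(iter(values.values())))
    cols = {"patient_id": ColumnInfo("id", "id")}
    data = {"patient_id": [f"p{i}" for i in range(n)]}
    for name, vals in values.items():
        kind = (kinds or {}).get(name, "continuous")
        group = "clinical" if name in ("age", "sex", "wbc") else "analyte"
        cols[name] = ColumnInfo(kind, group)
        data[name] = vals
    return CohortTable(df=pd.DataFrame(data), columns=cols)


class TestLogTransform:
    def test_log_values(self):
        t = make_table({"HGF": [1.0, 515.0, np.nan]})
        out = log_transform_analytes(t)
        got = out.df["HGF"].tolist()
        assert got[0] == pytest.approx(0.0)
        assert got[1] == pytest.approx(6.244, abs=5e-4)  # typical serum log HGF magnitude
        assert np.isnan(got[2])

    def test_floor_applies_before_log(self):
        t = make_table({"HGF": [0.0]})
        out = log_transform_analytes(t, floor=0.5)
        assert out.df["HGF"].iloc[0] == pytest.approx(np.log(0.5), abs=1e-9)

    def test_negative_value_names_cell(self):
        t = make_table({"HGF": [1.0, -2.0]})
        with pytest.raises(ValueError, match="HGF.*p1"):
            log_transform_analytes(t)

    def test_double_transform_refused(self):
        t = log_transform_analytes(make_table({"HGF": [1.0]}))
        with pytest.raises(ValueError, match="already"):
            log_transform_analytes(t)

    def test_clinical_columns_untouched(self):
        t = make_table({"HGF": [10.0], "age": [40.0]})
        out = log_transform_analytes(t)
        assert out.df["age"].iloc[0] == 40.0


class TestMissingFilter:
    def test_thirty_percent_dropped_twenty_kept(self):
        vals = {
            "a30": [np.nan] * 3 + [1.0] * 7,  # 30% > 20% -> dropped
            "a20": [np.nan] * 2 + [1.0] * 8,  # exactly 20% -> kept
            "a0": [1.0] * 10,
        }
        table, dropped = filter_missing_variables(make_table(vals))
        assert dropped == ["a30"]
        assert "a20" in table.df.columns and "a0" in table.df.columns

    def test_randomized_exactness(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            values = {}
            for j in range(int(rng.integers(2, 8))):
                col = rng.uniform(1, 2, size=n)
                col[rng.uniform(size=n) < rng.uniform(0, 0.5)] = np.nan
                values[f"v{j}"] = col.tolist()
            t = make_table(values)
            out, dropped = filter_missing_variables(t, 0.20)
            for v in values:
                frac = float(np.isnan(np.array(values[v])).mean())
                assert (v in dropped) == (frac > 0.20)

    def test_empty_table_passes_through(self):
        t = make_table({"a": []})
        out, dropped = filter_missing_variables(t)
        assert dropped == [] and "a" in out.df.columns


class TestDiscretizer:
    def test_tertile_cuts_match_quantile_oracle(self):
        t = make_table({"x": list(map(float, range(1, 10)))})
        dmap = fit_discretizer(t, bins=3)
        expected = np.quantile(np.arange(1.0, 10.0), [1 / 3, 2 / 3])
        assert dmap.cuts["x"] == pytest.approx(list(expected), abs=1e-9)
        assert dmap.assign("x", 5.0) == 1  # middle bin

    def test_training_bins_balanced(self):
        t = make_table({"x": list(map(float, range(1, 10)))})
        dmap = fit_discretizer(t, bins=3)
        codes = apply_discretizer(dmap, t)["x"]
        counts = codes.value_counts()
        assert sorted(counts.tolist()) == [3, 3, 3]

    def test_constant_variable_single_bin_flagged(self):
        t = make_table({"x": [2.0] * 6})
        dmap = fit_discretizer(t, bins=3)
        assert dmap.cuts["x"] == [] and dmap.flags["x"] == "constant"
        assert dmap.bins_for("x") == 1

    def test_out_of_range_values_clamp(self):
        t = make_table({"x": list(map(float, range(1, 10)))})
        dmap = fit_discretizer(t, bins=3)
        assert dmap.assign("x", -100.0) == 0
        assert dmap.assign("x", 100.0) == 2

    def test_missing_stays_missing_and_empty_table(self):
        t = make_table({"x": [1.0, np.nan, 3.0, 4.0]})
        dmap = fit_discretizer(t, bins=2)
        codes = apply_discretizer(dmap, t)
        assert np.isnan(codes["x"].iloc[1])
        empty = make_table({"x": []})
        assert len(apply_discretizer(fit_discretizer(t, bins=2), empty)) == 0

    def test_all_missing_variable_flagged_unusable(self):
        t = make_table({"x": [np.nan, np.nan], "y": [1.0, 2.0]})
        dmap = fit_discretizer(t, bins=2)
        assert dmap.flags["x"] == "unusable" and "x" not in dmap.cuts
        assert "x" not in apply_discretizer(dmap, t).columns

    def test_no_leakage_from_held_out_rows(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 1000.0]
        t = make_table({"x": vals})
        train = [f"p{i}" for i in range(9)]  # p9 held out
        dmap1 = fit_discretizer(t, training_ids=train, bins=3)
        mutated = list(vals)
        mutated[9] = -999.0  # mutate the held-out value
        dmap2 = fit_discretizer(make_table({"x": mutated}), training_ids=train, bins=3)
        assert dmap1.cuts == dmap2.cuts

    def test_binary_passthrough(self):
        t = make_table({"sex": [0.0, 1.0, 1.0]}, kinds={"sex": "binary"})
        dmap = fit_discretizer(t, bins=3)
        codes = apply_discretizer(dmap, t)
        assert codes["sex"].tolist() == [0.0, 1.0, 1.0]

    def test_json_roundtrip(self, tmp_path):
        t = make_table({"x": [1.0, 2.0, 5.0, 9.0]})
        dmap = fit_discretizer(t, bins=3)
        dmap.to_json(tmp_path / "d.json")
        back = type(dmap).from_json(tmp_path / "d.json")
        assert back.cuts == dmap.cuts and back.n_bins == dmap.n_bins
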