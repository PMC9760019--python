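import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isospec.data import (
    IsotopeDataset,
    apply_ethanol_correction,
    correct_ethanol_preservation,
    lipid_correction_needed,
    read_baseline_table,
    read_consumer_table,
    screen_lipids,
    summarize_population,
)
from isospec.errors import (
    ConfigurationError,
    DomainError,
    IntegrityError,
    ParseError,
    SchemaError,
)


class TestReadConsumerTable:
    def test_round_trip_identity(self, tiny_dataset, tmp_path):
        path = tmp_path / "consumers.csv"
        tiny_dataset.to_csv(path)
        back = read_consumer_table(path)
        pd.testing.assert_frame_equal(back.table, tiny_dataset.table)
        assert len(back) == 4 and len(back.individuals) == 2

    def test_schema_mapping(self, tiny_table, tmp_path):
        renamed = tiny_table.rename(columns={"individual_id": "fish", "d13C": "delta13C"})
        path = tmp_path / "c.csv"
        renamed.to_csv(path, index=False)
        ds = read_consumer_table(path, schema={"individual_id": "fish", "d13C": "delta13C"})
        assert ds.individuals == ["U1", "U2"]

    def test_missing_column_is_schema_error(self, tiny_table, tmp_path):
        path = tmp_path / "c.csv"
        tiny_table.drop(columns=["d15N"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="d15N"):
            read_consumer_table(path)

    def test_duplicate_individual_tissue_rejected(self, tiny_table):
        dup = pd.concat([tiny_table, tiny_table.iloc[[0]]], ignore_index=True)
        with pytest.raises(IntegrityError, match=r"U1.*muscle"):
            IsotopeDataset(dup)

    def test_non_numeric_isotope_names_row(self, tiny_table, tmp_path):
        bad = tiny_table.copy()
        bad.loc[2, "d13C"] = "oops"
        path = tmp_path / "c.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ParseError, match="row 2"):
            read_consumer_table(path)

    @pytest.mark.parametrize("col,val", [("d13C", -75.0), ("d13C", 5.0),
                                         ("d15N", -20.0), ("d15N", 40.0)])
    def test_isotope_plausibility_window(self, tiny_table, col, val):
        bad = tiny_table.copy()
        bad.loc[0, col] = val
        with pytest.raises(DomainError, match="plausibility"):
            IsotopeDataset(bad)

    def test_unknown_tissue_rejected(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[0, "tissue"] = "liver"
        with pytest.raises(DomainError, match="liver"):
            IsotopeDataset(bad)

    def test_baseline_aggregates_replicates(self, tmp_path):
        path = tmp_path / "base.csv"
        pd.DataFrame({"site": ["A", "A", "B"], "d15N_base": [5.0, 6.0, 3.0]}).to_csv(
            path, index=False)
        recs = {r.site: r.d15N_base for r in read_baseline_table(path)}
        assert recs == {"A": 5.5, "B": 3.0}


class TestEthanolCorrection:
    @given(st.lists(st.floats(-60, 0), min_size=1, max_size=10))
    def test_identity_coefficients(self, values):
        out = correct_ethanol_preservation(values, "d13C", (0.0, 1.0))
        assert np.allclose(out, values)

    def test_additive_shift(self):
        out = correct_ethanol_preservation([-30.0, -32.0], "d13C", (1.0, 1.0))
        assert np.allclose(out, [-29.0, -31.0])

    def test_affine_hand_value(self):
        out = correct_ethanol_preservation([-30.0], "d13C", (-0.5, 1.02))
        assert np.allclose(out, [-31.1])

    def test_missing_coefficients_is_config_error(self):
        with pytest.raises(ConfigurationError):
            correct_ethanol_preservation([-30.0], "d13C", None)

    def test_dataset_level_application_records_metadata(self, tiny_dataset):
        with pytest.warns(UserWarning, match="already corrected"):
            same = apply_ethanol_correction(tiny_dataset, None)
        assert same.metadata["corrections"][0]["applied"] is False
        shifted = apply_ethanol_correction(tiny_dataset, {"d13C": (1.0, 1.0)}, tissue="fin")
        fin = shifted.table[shifted.table.tissue == "fin"]["d13C"].to_numpy()
        orig = tiny_dataset.table[tiny_dataset.table.tissue == "fin"]["d13C"].to_numpy()
        assert np.allclose(fin, orig + 1.0)
        assert shifted.metadata["corrections"][0]["applied"] is True


class TestLipidScreen:
    @pytest.mark.parametrize("ratio,flag", [(3.2, False), (3.5, True), (10.0, True)])
    def test_threshold_inclusive(self, ratio, flag):
        assert lipid_correction_needed(ratio) is flag

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(DomainError):
            lipid_correction_needed(-1.0)

    def test_screen_refuses_flagged_samples(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[0, "cn_ratio"] = 4.2
        ds = IsotopeDataset(bad)
        with pytest.raises(DomainError, match="lipid"):
            screen_lipids(ds, on_flag="error")
        with pytest.warns(UserWarning):
            screened = screen_lipids(ds, on_flag="warn")
        assert screened.metadata["lipid_screen"]["n_flagged"] == 1


class TestSummarizePopulation:
    def test_identical_rows_have_zero_sd(self):
        t = pd.DataFrame({
            "individual_id": ["a", "b"], "site": ["S", "S"],
            "tissue": ["muscle", "muscle"], "d13C": [-35.0, -35.0],
            "d15N": [10.0, 10.0],
        })
        s = summarize_population(IsotopeDataset(t))
        assert s.loc[0, "d13C_mean"] == -35.0 and s.loc[0, "d13C_sd"] == 0.0

    def test_hand_computed_sample_sd(self):
        t = pd.DataFrame({
            "individual_id": ["a", "b"], "site": ["S", "S"],
            "tissue": ["muscle", "muscle"], "d13C": [-34.0, -36.0],
            "d15N": [10.0, 12.0],
        })
        s = summarize_population(IsotopeDataset(t))
        assert s.loc[0, "d13C_mean"] == -35.0
        assert s.loc[0, "d13C_sd"] == pytest.approx(np.sqrt(2.0))

    def test_singleton_group_flagged(self, tiny_table):
        t = tiny_table.drop(index=[1]).reset_index(drop=True)  # U1 muscle only
        s = summarize_population(IsotopeDataset(t))
        fin = s[s.tissue == "fin"].iloc[0]
        assert fin["n"] == 1 and not fin["sd_defined"] and np.isnan(fin["d13C_sd"])

    def test_self_concatenation_keeps_means_doubles_n(self, tiny_dataset):
        relabeled = tiny_dataset.table.copy()
        relabeled["individual_id"] = relabeled["individual_id"] + "_copy"
        doubled = IsotopeDataset(
            pd.concat([tiny_dataset.table, relabeled], ignore_index=True))
        s1 = summarize_population(tiny_dataset).set_index(["site", "tissue"])
        s2 = summarize_population(doubled).set_index(["site", "tissue"])
        assert (s2["n"] == 2 * s1["n"]).all()
        assert np.allclose(s2["d13C_mean"], s1["d13C_mean"])
        assert np.allclose(s2["d15N_mean"], s1["d15N_mean"])
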