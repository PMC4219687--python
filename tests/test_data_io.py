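"""Loaders, validation diagnostics and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from conftest import exposure_frame, mortality_frame, rr_frame
from pafineq.data import (AnalysisConfig, ExposureTable, RelativeRiskTable,
                          SchemaError, StratifiedMortality, ValidationError,
                          load_exposure, load_mortality, load_relative_risks)


class TestMortality:
    def test_full_grid_cardinality(self):
        m = StratifiedMortality.from_frame(mortality_frame(("A", "B", "C")))
        assert len(m.data) == 3 * 2 * 3 * 4

    def test_deaths_exceeding_person_years_named(self):
        df = mortality_frame()
        df.loc[5, "deaths"] = df.loc[5, "person_years"] + 1
        with pytest.raises(ValidationError, match="deaths exceed person_years"):
            StratifiedMortality.from_frame(df)

    def test_rate_definition(self):
        df = mortality_frame(deaths=5.0, person_years=100_000.0)
        m = StratifiedMortality.from_frame(df)
        assert m.rates()["rate"].iloc[0] == pytest.approx(5.0)

    def test_unknown_education_label_is_schema_error(self):
        df = mortality_frame()
        df.loc[0, "education"] = "phd"
        with pytest.raises(SchemaError, match="phd"):
            StratifiedMortality.from_frame(df)

    def test_incomplete_grid_rejected(self):
        df = mortality_frame().drop(index=[0])
        with pytest.raises(ValidationError, match="incomplete"):
            StratifiedMortality.from_frame(df)

    def test_negative_deaths_rejected(self):
        df = mortality_frame()
        df.loc[2, "deaths"] = -1
        with pytest.raises(ValidationError, match="negative deaths"):
            StratifiedMortality.from_frame(df)

    def test_standard_weights_sum_to_one(self):
        m = StratifiedMortality.from_frame(mortality_frame())
        w = m.standard_weights("A", "men")
        assert w.sum() == pytest.approx(1.0)

    def test_en_dash_age_labels_accepted(self):
        df = mortality_frame()
        df["age_group"] = df["age_group"].str.replace("-", "–")
        m = StratifiedMortality.from_frame(df)
        assert set(m.data["age_group"]) == {"30-44", "45-59", "60-69", "70-79"}


class TestExposure:
    def test_valid_distribution_accepted_and_renormalised(self):
        e = ExposureTable.from_frame(
            exposure_frame({"low": [0.5, 0.3, 0.2], "mid": [0.5, 0.3, 0.2],
                            "high": [0.5, 0.3, 0.2]}))
        d = e.distributions("A", "men", "low", "smoking")
        assert d.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-15)
        assert e.categories["smoking"] == ["never", "former", "current"]

    def test_sum_far_from_one_rejected_with_stratum(self):
        df = exposure_frame({"low": [0.5, 0.3, 0.17], "mid": [0.5, 0.3, 0.2],
                             "high": [0.5, 0.3, 0.2]})
        with pytest.raises(ValidationError, match="low"):
            ExposureTable.from_frame(df)

    def test_absent_population_factor_marked_unavailable(self):
        df = pd.concat([
            exposure_frame({"low": [0.5, 0.5], "mid": [0.5, 0.5],
                            "high": [0.5, 0.5]}, populations=("A", "B"),
                           risk_factor="inactivity",
                           categories=["active", "sedentary"]),
            exposure_frame({"low": [0.5, 0.3, 0.2], "mid": [0.5, 0.3, 0.2],
                            "high": [0.5, 0.3, 0.2]}, populations=("A",)),
        ])
        e = ExposureTable.from_frame(df)
        assert e.available("A", "men", "smoking")
        assert not e.available("B", "men", "smoking")

    def test_partial_stratum_rejected(self):
        df = exposure_frame({"low": [0.5, 0.3, 0.2], "mid": [0.5, 0.3, 0.2],
                             "high": [0.5, 0.3, 0.2]}).drop(index=[0, 1, 2])
        with pytest.raises(ValidationError, match="partial"):
            ExposureTable.from_frame(df)

    def test_missing_survey_n_rejected_with_hint(self):
        df = exposure_frame({"low": [0.5, 0.3, 0.2], "mid": [0.5, 0.3, 0.2],
                             "high": [0.5, 0.3, 0.2]})
        df.loc[3, "survey_n"] = np.nan
        with pytest.raises(ValidationError, match="survey_n"):
            ExposureTable.from_frame(df)


class TestRelativeRisks:
    def test_lookup_and_reference(self):
        rr = RelativeRiskTable.from_frame(rr_frame())
        assert rr.reference("smoking") == "never"
        assert rr.lookup("smoking", "current", "men", "30-44") == 2.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValidationError, match="> 0"):
            RelativeRiskTable.from_frame(rr_frame(rrs=[1.0, -1.0, 2.0]))

    def test_duplicate_keys_rejected(self):
        df = pd.concat([rr_frame(), rr_frame().iloc[[2]]])
        with pytest.raises(ValidationError, match="duplicate"):
            RelativeRiskTable.from_frame(df)

    def test_age_specific_rows_win_over_broadcast(self):
        df = rr_frame()
        df = pd.concat([df, pd.DataFrame([
            {"risk_factor": "smoking", "category": "current", "sex": "men",
             "age_group": "30-44", "rr": 2.8}])], ignore_index=True)
        rr = RelativeRiskTable.from_frame(df)
        assert rr.lookup("smoking", "current", "men", "30-44") == 2.8
        assert rr.lookup("smoking", "current", "men", "45-59") == 2.0
        assert rr.lookup("smoking", "current", "women", "30-44") == 2.0

    def test_reference_rr_must_be_one(self):
        with pytest.raises(ValidationError, match="reference"):
            RelativeRiskTable.from_frame(rr_frame(rrs=[1.1, 1.3, 2.0]))


class TestRoundTrip:
    def test_csv_round_trip_bit_identical(self, tmp_path, toy_dataset):
        mort, exp, rr = toy_dataset
        mort.to_csv(tmp_path / "m.csv", header_lines=["demo"])
        exp.to_csv(tmp_path / "e.csv")
        rr.to_csv(tmp_path / "r.csv")
        m2 = load_mortality(tmp_path / "m.csv")
        e2 = load_exposure(tmp_path / "e.csv")
        r2 = load_relative_risks(tmp_path / "r.csv")
        pd.testing.assert_frame_equal(mort.data, m2.data)
        pd.testing.assert_frame_equal(exp.data, e2.data)
        assert r2.lookup("smoking", "current", "men", "30-44") == 2.0

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = AnalysisConfig(scenario="best_practice", risk_factor="smoking",
                             bootstrap_b=250, seed=11, precision=1,
                             donors={"smoking": {"men": "A"}})
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = AnalysisConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_invalid_bootstrap_count_rejected(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(bootstrap_b=0)
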