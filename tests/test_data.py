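"""Data model, I/O, validation and analysis-set preparation."""

import numpy as np
import pandas as pd
import pytest

from nbsides.data import (
    BIOMARKERS,
    SchemaError,
    Subgroup,
    TrialDataset,
    ValidationError,
    covariate_associations,
    exclusion_log,
    load_trial,
    prepare_analysis_set,
    save_trial,
    summarize_baseline,
)
from nbsides.simulate import ScenarioConfig, simulate_trial


class TestLoadTrial:
    def test_roundtrip_lossless(self, tiny_participants, tmp_path):
        df = tiny_participants.copy()
        df.loc[0, "feno_ppb"] = np.nan  # missingness must survive the roundtrip
        path = tmp_path / "p.csv"
        save_trial(TrialDataset(df), path)
        back = load_trial(path)
        pd.testing.assert_frame_equal(
            back.participants, df, check_dtype=False, check_exact=False
        )
        assert np.isnan(back.participants.loc[0, "feno_ppb"])

    def test_missing_required_column_names_it(self, tiny_participants, tmp_path):
        df = tiny_participants.drop(columns=["followup_years"])
        path = tmp_path / "p.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="followup_years"):
            load_trial(path)

    def test_negative_followup_cites_participant(self, tiny_participants, tmp_path):
        df = tiny_participants.copy()
        df.loc[3, "followup_years"] = -0.1
        path = tmp_path / "p.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match=str(df.loc[3, "participant_id"])):
            load_trial(path)

    def test_visit_orphan_rejected(self, tiny_participants):
        visits = pd.DataFrame(
            {"participant_id": ["GHOST"], "endpoint": ["acq6"], "week": [52],
             "value": [1.0]}
        )
        with pytest.raises(ValidationError, match="GHOST"):
            TrialDataset(tiny_participants, visits)

    def test_schema_mapping(self, tiny_participants, tmp_path):
        df = tiny_participants.rename(columns={"followup_years": "fu_yrs"})
        path = tmp_path / "p.csv"
        df.to_csv(path, index=False)
        data = load_trial(path, schema={"fu_yrs": "followup_years"})
        assert "followup_years" in data.participants.columns


class TestPrepareAnalysisSet:
    def test_placebo_pooling_merges_sizes(self, tiny_dataset):
        prep = prepare_analysis_set(tiny_dataset)
        counts = prep.arm_counts()
        assert counts["placebo"] == 6
        assert set(prep.participants["arm"]) == {"tralo_q2w", "tralo_q4w", "placebo"}

    def test_outlier_rule_removes_and_logs(self, tiny_participants):
        df = tiny_participants.copy()
        df.loc[0, "eos_cells_ul"] = 7510.0
        df.loc[5, "eos_cells_ul"] = 4130.0
        prep = prepare_analysis_set(
            TrialDataset(df), outlier_rules=[("eos_cells_ul", 4000.0)]
        )
        log = exclusion_log(prep)
        assert len(log) == 2
        assert sorted(log["value"]) == [4130.0, 7510.0]
        assert prep.n == len(df) - 2

    def test_unknown_biomarker_rule_rejected(self, tiny_dataset):
        with pytest.raises(SchemaError, match="not_a_marker"):
            prepare_analysis_set(tiny_dataset, outlier_rules=[("not_a_marker", 1.0)])

    def test_empty_rules_only_pools(self, tiny_dataset):
        prep = prepare_analysis_set(tiny_dataset, outlier_rules=[])
        assert prep.n == tiny_dataset.n
        assert exclusion_log(prep).empty

    def test_outcomes_untouched_and_log_length(self, tiny_participants):
        df = tiny_participants.copy()
        df.loc[2, "feno_ppb"] = 400.0
        data = TrialDataset(df)
        prep = prepare_analysis_set(data, outlier_rules=[("feno_ppb", 300.0)])
        assert len(exclusion_log(prep)) == data.n - prep.n
        merged = prep.participants.merge(
            df[["participant_id", "exacerbation_count", "followup_years"]],
            on="participant_id", suffixes=("", "_orig"),
        )
        assert (merged["exacerbation_count"] == merged["exacerbation_count_orig"]).all()
        assert (merged["followup_years"] == merged["followup_years_orig"]).all()

    def test_derived_covariates(self, tiny_dataset):
        prep = prepare_analysis_set(tiny_dataset)
        p = prep.participants
        adol = p["age_years"] < 18
        assert (p.loc[adol, "age_group"] == "adolescent").all()
        assert (p.loc[~adol, "age_group"] == "adult").all()
        assert set(p["prior_exac_cat"]) <= {"1", "2", ">=3"}
        assert set(p["periostin_group"].dropna()) <= {"high", "low"}


class TestSummaries:
    def test_single_value_stats(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a"],
                "arm": ["tralo_q2w"],
                "feno_ppb": [20.0],
                "exacerbation_count": [0],
                "followup_years": [1.0],
            }
        )
        tab = summarize_baseline(TrialDataset(df), biomarkers=["feno_ppb"])
        row = tab.iloc[0]
        assert row["n"] == 1 and row["mean"] == 20.0 and row["median"] == 20.0
        assert np.isnan(row["sd"])
        assert (row["min"], row["max"]) == (20.0, 20.0)

    def test_matches_brute_force(self, planted_prepared):
        prep, _ = planted_prepared
        tab = summarize_baseline(prep)
        assert len(tab) == 5 * 3  # 5 biomarkers x 3 pooled arms
        for _, row in tab.sample(6, random_state=0).iterrows():
            v = prep.participants.loc[
                prep.participants["arm"] == row["arm"], row["biomarker"]
            ].dropna().to_numpy()
            assert row["n"] == len(v)
            assert row["mean"] == pytest.approx(v.mean())
            assert row["sd"] == pytest.approx(v.std(ddof=1))
            assert row["median"] == pytest.approx(np.median(v))

    def test_n_sums_to_nonmissing_total(self, planted_prepared):
        prep, _ = planted_prepared
        tab = summarize_baseline(prep)
        for bm in BIOMARKERS:
            total = tab.loc[tab["biomarker"] == bm, "n"].sum()
            assert total == prep.participants[bm].notna().sum()


class TestCovariateAssociations:
    def test_planted_region_shift_detected(self):
        cfg = ScenarioConfig(
            name="shift", n_total=1500, endpoints={},
            region_shift=("periostin_ng_ml", "asia_pacific", 1.5),
        )
        data, _ = simulate_trial(cfg, seed=11)
        prep = prepare_analysis_set(data)
        tab = covariate_associations(prep, ["region"], biomarkers=["periostin_ng_ml"])
        med = tab.set_index("level")["median"]
        others = [r for r in med.index if r != "asia_pacific"]
        assert med["asia_pacific"] > max(med[r] for r in others)

    def test_single_level_equals_overall(self, tiny_participants):
        df = tiny_participants.copy()
        df["region"] = "europe"
        tab = covariate_associations(TrialDataset(df), ["region"])
        for bm in BIOMARKERS:
            row = tab[tab["biomarker"] == bm].iloc[0]
            assert row["median"] == pytest.approx(df[bm].median())

    def test_continuous_covariate_rejected(self, tiny_dataset):
        with pytest.raises(SchemaError, match="age_years"):
            covariate_associations(tiny_dataset, ["age_years"])


class TestSubgroup:
    def test_partition_of_nonmissing(self, tiny_participants):
        df = tiny_participants.copy()
        df.loc[1, "feno_ppb"] = np.nan
        sub = Subgroup("feno_ppb", "above", float(df["feno_ppb"].median()))
        inside = sub.mask(df)
        outside = sub.complement().mask(df)
        assert not (inside & outside).any()
        assert (inside | outside).sum() == df["feno_ppb"].notna().sum()

    def test_labels(self):
        assert Subgroup("feno_ppb", "above", 32.3).label == "FeNO > 32.3 ppb"
        assert Subgroup("feno_ppb", "above", 37, inclusive=True).label == "FeNO >= 37 ppb"
        assert Subgroup("feno_ppb", "at_or_below", 32.3).label == "FeNO <= 32.3 ppb"
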