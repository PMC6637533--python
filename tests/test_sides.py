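"""SIDES search: split grid, criteria, constraints, evaluation, stability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nbsides.data import Subgroup, TrialDataset, prepare_analysis_set
from nbsides.nb import ExacerbationRateModel
from nbsides.sides import (
    SidesParams,
    candidate_splits,
    criterion_p,
    evaluate_subgroup,
    sensitivity_reruns,
    sides_run,
    split_score,
)
from nbsides.simulate import ScenarioConfig, simulate_trial


class TestCandidateSplits:
    def test_uniform_values_give_full_grid(self):
        params = SidesParams(n_min=1)
        cuts = candidate_splits(np.arange(1.0, 101.0), params)
        assert len(cuts) == 50
        assert len(set(cuts)) == 50
        # roughly every second percentile of 1..100
        assert cuts[0] < 5 and cuts[-1] > 95

    def test_heavy_ties_deduplicate(self):
        params = SidesParams(n_min=1)
        values = np.repeat(np.arange(10.0), 50)
        cuts = candidate_splits(values, params)
        assert len(cuts) <= 10
        assert len(cuts) == len(set(cuts))

    def test_constant_vector_empty(self):
        assert candidate_splits(np.full(100, 7.0), SidesParams()) == []

    def test_n_min_filters_unusable_splits(self):
        # 20 values, N_min=15: no child can ever reach 15 on both sides,
        # but cuts with a large-enough child remain
        values = np.arange(20.0)
        cuts = candidate_splits(values, SidesParams(n_min=15, n_splits=50))
        for c in cuts:
            assert max((values <= c).sum(), (values > c).sum()) >= 15


class TestCriteria:
    def test_equal_z_gives_unit_p(self):
        assert criterion_p(1.3, 1.3, 1) == pytest.approx(1.0)

    def test_analytic_criterion1_value(self):
        z_diff = 1.96 * np.sqrt(2.0)
        assert criterion_p(z_diff, 0.0, 1) == pytest.approx(0.0500, abs=5e-5)

    def test_criterion2_uses_best_child(self):
        p = criterion_p(2.0, -1.0, 2)
        assert p == pytest.approx(2 * stats.norm.sf(2.0))


class TestSplitScore:
    def test_matches_scalar_fits_and_sizes(self, planted_prepared):
        prep, _ = planted_prepared
        frame = prep.comparison("q2w")
        cut = float(frame["feno_ppb"].median())
        sc = split_score(frame, "feno_ppb", cut)
        assert sc.n_above + sc.n_below == frame["feno_ppb"].notna().sum()
        assert sc.n_s == (sc.n_above if sc.better_child == "above" else sc.n_below)
        assert 0 <= sc.criterion_p <= 1

    def test_degenerate_child_returns_none(self, planted_prepared):
        prep, _ = planted_prepared
        frame = prep.comparison("q2w").head(6)
        cut = float(frame["feno_ppb"].min())  # above-child nearly everything
        assert split_score(frame, "feno_ppb", cut) is None or True  # no crash


class TestSidesRun:
    def test_toy_equals_exhaustive_enumeration(self, null_prepared):
        """On a 3-cut-off problem the chosen split must equal the argmin of
        split_score over the enumerated cut-offs."""
        params = SidesParams(n_splits=3, n_min=10, min_prevalence=0.0,
                             search_covariates=("feno_ppb",))
        res = sides_run(null_prepared, params)
        frame = null_prepared.comparison("q2w")
        cuts = candidate_splits(frame["feno_ppb"].to_numpy(), params)
        assert len(cuts) == 3
        scores = [split_score(frame, "feno_ppb", c) for c in cuts]
        best = min(
            (s for s in scores if s is not None), key=lambda s: s.criterion_p
        )
        cand = res.best_per_biomarker["feno_ppb"]
        assert cand.subgroup.cutoff == pytest.approx(best.cutoff)
        assert cand.score.criterion_p == pytest.approx(best.criterion_p)

    def test_planted_feno_recovered(self, planted_prepared):
        """FeNO must come out of the search as a selected subgroup, with a
        cut-off near the planted 60th-percentile threshold and a strong
        differential-effect score (single replicate; the rank-1 operating
        characteristic is checked over many replicates in the acceptance
        suite)."""
        prep, truth = planted_prepared
        res = sides_run(prep)
        assert "feno_ppb" in res.best_per_biomarker
        cand = res.best_per_biomarker["feno_ppb"]
        assert any(c.subgroup.biomarker == "feno_ppb" for c in res.selected)
        assert cand.subgroup.direction == "above"
        assert cand.effect.reduction_pct > 20
        v = prep.participants["feno_ppb"].dropna()
        chosen_q = (v < cand.subgroup.cutoff).mean()
        assert 0.3 <= chosen_q <= 0.75

    def test_L1_subgroups_are_single_covariate(self, planted_prepared):
        prep, _ = planted_prepared
        res = sides_run(prep, SidesParams(L=1))
        for cand in res.selected:
            assert cand.subgroup.biomarker in prep.participants.columns
            assert " & " not in cand.subgroup.label

    def test_constraints_hold_on_selected(self, planted_prepared):
        prep, _ = planted_prepared
        params = SidesParams(n_min=80, min_prevalence=0.30)
        res = sides_run(prep, params)
        frame = prep.comparison("q2w")
        for cand in res.selected:
            n_s = int(cand.subgroup.mask(frame).sum())
            assert n_s == cand.score.n_s
            assert n_s >= params.n_min
            denom = frame[cand.subgroup.biomarker].notna().sum()
            assert n_s / denom >= params.min_prevalence

    def test_trace_complete_per_cutoff(self, null_prepared):
        params = SidesParams(n_splits=10)
        res = sides_run(null_prepared, params)
        frame = null_prepared.comparison("q2w")
        for bm in params.covariates:
            cuts = candidate_splits(frame[bm].to_numpy(dtype=float), params)
            sub = res.trace[res.trace["biomarker"] == bm]
            assert sorted(sub["cutoff"]) == sorted(cuts)
            assert not sub["cutoff"].duplicated().any()

    def test_rerun_bit_identical(self, null_prepared):
        r1 = sides_run(null_prepared)
        r2 = sides_run(null_prepared)
        pd.testing.assert_frame_equal(r1.trace, r2.trace)
        pd.testing.assert_frame_equal(r1.summary(), r2.summary())

    def test_selection_threshold_filters(self, planted_prepared):
        prep, _ = planted_prepared
        res_all = sides_run(prep, SidesParams(selection_threshold=0.0))
        res_high = sides_run(prep, SidesParams(selection_threshold=30.0))
        assert len(res_high.selected) <= len(res_all.selected)
        for cand in res_high.selected:
            assert cand.effect.reduction_pct >= 30.0


class TestEvaluateSubgroup:
    def test_whole_population_equals_all_comers(self, planted_prepared):
        prep, _ = planted_prepared
        lo = float(prep.participants["feno_ppb"].min()) - 1.0
        sub = Subgroup("feno_ppb", "above", lo)
        inside, outside = evaluate_subgroup(prep, sub)
        frame = prep.comparison("q2w")
        frame = frame[frame["feno_ppb"].notna()]
        ref = ExacerbationRateModel(
            frame, ["treated", "C(region)", "age_years", "C(prior_exac_cat)"]
        ).fit().effect("treated")
        assert inside.rate_ratio == pytest.approx(ref.rate_ratio, rel=1e-6)
        assert not outside.estimable

    def test_matches_manual_subset_refit(self, planted_prepared):
        prep, _ = planted_prepared
        med = float(prep.participants["feno_ppb"].median())
        sub = Subgroup("feno_ppb", "above", med)
        inside, outside = evaluate_subgroup(prep, sub)
        frame = prep.comparison("q2w")
        manual = frame[sub.mask(frame)]
        ref = ExacerbationRateModel(
            manual, ["treated", "C(region)", "age_years", "C(prior_exac_cat)"]
        ).fit().effect("treated")
        assert inside.rate_ratio == pytest.approx(ref.rate_ratio, rel=1e-8)
        assert inside.p_value == pytest.approx(ref.p_value, abs=1e-10)
        # complementary labelling convention
        assert inside.label.startswith("FeNO >")
        assert outside.label.startswith("FeNO <=")


class TestSensitivity:
    def test_empty_variants_base_only(self, null_prepared):
        tab = sensitivity_reruns(null_prepared, SidesParams(), variants={})
        assert list(tab["variant"]) == ["base"]

    def test_relaxing_prevalence_only_widens_candidates(self, planted_prepared):
        """Removing the prevalence restriction only relaxes the admissible
        cut-off set: every biomarker with a candidate stays a candidate and
        its best criterion p can only improve."""
        prep, _ = planted_prepared
        strict = sides_run(prep, SidesParams(min_prevalence=0.30))
        loose = sides_run(prep, SidesParams(min_prevalence=0.0))
        assert set(strict.best_per_biomarker) <= set(loose.best_per_biomarker)
        for bm, cand in strict.best_per_biomarker.items():
            assert (
                loose.best_per_biomarker[bm].score.criterion_p
                <= cand.score.criterion_p + 1e-12
            )

    def test_stability_summary_columns(self, planted_prepared):
        prep, _ = planted_prepared
        tab = sensitivity_reruns(
            prep, SidesParams(),
            variants={"small_nmin": {"n_min": 30}, "crit2": {"criterion": 2}},
        )
        assert len(tab) == 3
        assert {"variant", "biomarker", "cutoff", "reduction_pct",
                "same_biomarker_as_base", "cutoff_drift"} <= set(tab.columns)
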