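"""Seven-metric classification, composite scores and derived covariates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_records
from pedcvh import scoring
from pedcvh.references import bmi_cutoffs, bp_cutoffs
from pedcvh.scoring import (IDEAL, INTERMEDIATE, METRICS, POOR,
                            ParticipantRecord, build_profile, classify_bmi,
                            classify_bp, classify_diet, classify_fbg,
                            classify_physical_activity, classify_smoking,
                            classify_tc, compute_bmi, derive_covariates,
                            derive_covariates_frame, parental_weight_status,
                            passive_smoking, profile_from_statuses,
                            score_cohort, score_diet_components,
                            sleep_adequate)


class TestBMI:
    def test_formula(self):
        assert compute_bmi(50, 160) == pytest.approx(19.531, abs=1e-3)
        assert compute_bmi(1, 100) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(0, 160)
        with pytest.raises(ValueError):
            compute_bmi(50, -1)

    @pytest.mark.parametrize("bmi,expected", [
        (17.9, IDEAL),          # strictly below p85
        (18.0, INTERMEDIATE),   # exactly at p85
        (21.0, INTERMEDIATE),   # exactly at p95
        (21.1, POOR),           # strictly above p95
    ])
    def test_percentile_bands(self, bmi, expected):
        assert classify_bmi(bmi, p85=18.0, p95=21.0) == expected


class TestSimpleMetrics:
    @pytest.mark.parametrize("smoked,expected", [
        (True, POOR), (False, IDEAL), (None, None)])
    def test_smoking_binary(self, smoked, expected):
        assert classify_smoking(smoked) == expected

    @pytest.mark.parametrize("minutes,expected", [
        (75, IDEAL), (60, IDEAL), (59.9, INTERMEDIATE), (30, INTERMEDIATE),
        (0.1, INTERMEDIATE), (0, POOR), (None, None)])
    def test_physical_activity(self, minutes, expected):
        assert classify_physical_activity(minutes) == expected

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            classify_physical_activity(-5)

    @pytest.mark.parametrize("tc,expected", [
        (150, IDEAL), (169.99, IDEAL), (170, INTERMEDIATE), (185, INTERMEDIATE),
        (199.5, INTERMEDIATE), (200, POOR), (260, POOR)])
    def test_total_cholesterol(self, tc, expected):
        assert classify_tc(tc) == expected

    @pytest.mark.parametrize("fbg,expected", [
        (99, IDEAL), (99.9, IDEAL), (100, INTERMEDIATE), (125.9, INTERMEDIATE),
        (126, POOR)])
    def test_fasting_glucose(self, fbg, expected):
        assert classify_fbg(fbg) == expected

    @given(st.floats(min_value=1e-3, max_value=500.0,
                     allow_nan=False, allow_infinity=False))
    @settings(derandomize=True, max_examples=200)
    def test_every_positive_lab_value_gets_exactly_one_status(self, value):
        assert classify_tc(value) in (POOR, INTERMEDIATE, IDEAL)
        assert classify_fbg(value) in (POOR, INTERMEDIATE, IDEAL)


class TestDiet:
    def test_all_components_at_their_inclusive_limits(self):
        # fried <= 1/week is inclusive, SSB < 1/week strict
        assert score_diet_components(1, 1, 1, 0, 1) == 5
        assert score_diet_components(1, 1, 1, 1, 1) == 4
        assert score_diet_components(0, 0, 2, 2, 0) == 0

    def test_missing_component_makes_metric_missing(self):
        assert score_diet_components(1, None, 1, 0, 1) is None

    @pytest.mark.parametrize("count,expected", [
        (5, IDEAL), (4, IDEAL), (3, INTERMEDIATE), (2, INTERMEDIATE),
        (1, POOR), (0, POOR)])
    def test_band_mapping(self, count, expected):
        assert classify_diet(count) == expected

    def test_out_of_range_count_rejected(self):
        with pytest.raises(ValueError):
            classify_diet(6)


class TestBloodPressure:
    CUTS = (110.0, 115.0, 72.0, 76.0)

    @pytest.mark.parametrize("sbp,dbp,cuts,expected", [
        (105, 65, CUTS, IDEAL),
        (121, 65, (122.0, 126.0, 72.0, 76.0), INTERMEDIATE),  # absolute rule
        (116, 65, CUTS, POOR),                                 # sbp > p95
        (110, 65, CUTS, INTERMEDIATE),                         # at p90
        (105, 77, CUTS, POOR),                                 # dbp > p95
        (105, 80, (110.0, 115.0, 82.0, 85.0), INTERMEDIATE),   # dbp >= 80
        (None, 65, CUTS, None),
    ])
    def test_rules(self, sbp, dbp, cuts, expected):
        assert classify_bp(sbp, dbp, cuts) == expected


def _all_status_combos():
    smoking = (POOR, IDEAL)
    others = itertools.product((POOR, INTERMEDIATE, IDEAL), repeat=6)
    for s, rest in itertools.product(smoking, others):
        yield dict(zip(METRICS, (s, *rest)))


class TestCompositeScores:
    def test_all_ideal_profile(self):
        statuses = {m: IDEAL for m in METRICS}
        p = profile_from_statuses("x", statuses, diet_count=5)
        assert (p.cvh_score, p.behavior_score, p.factor_score) == (7, 4, 3)
        assert p.cvh_category == IDEAL
        assert p.ideal_behaviors and p.ideal_factors

    def test_behaviors_only_profile(self):
        statuses = {m: POOR for m in METRICS}
        statuses.update({"smoking": IDEAL, "diet": IDEAL,
                         "physical_activity": IDEAL})
        p = profile_from_statuses("x", statuses)
        assert p.cvh_score == 3 and p.cvh_category == INTERMEDIATE
        assert p.ideal_behaviors and not p.ideal_factors

    def test_missing_metric_invalidates(self):
        statuses = {m: IDEAL for m in METRICS}
        statuses["total_cholesterol"] = None
        p = profile_from_statuses("x", statuses)
        assert not p.valid
        assert p.missing_metrics == ("total_cholesterol",)
        assert p.cvh_score is None

    def test_score_decomposition_and_partition_exhaustive(self):
        """cvh = behavior + factor, categories partition {0..7} into
        0-2/3-5/6-7, and the ideal flags are consistent, over all
        2 x 3^6 status combinations."""
        seen_scores = set()
        for statuses in _all_status_combos():
            p = profile_from_statuses("x", statuses)
            assert p.valid
            assert p.cvh_score == p.behavior_score + p.factor_score
            expected_cat = (IDEAL if p.cvh_score >= 6 else
                            INTERMEDIATE if p.cvh_score >= 3 else POOR)
            assert p.cvh_category == expected_cat
            assert p.ideal_behaviors == (p.behavior_score in (3, 4))
            assert p.ideal_factors == (p.factor_score == 3)
            seen_scores.add(p.cvh_score)
        assert seen_scores == set(range(8))


RANK = {POOR: 0, INTERMEDIATE: 1, IDEAL: 2}


class TestVectorizedAgreesWithScalarAndBruteForce:
    def test_three_way_agreement_on_randomized_records(self, refs):
        """score_cohort (vectorized), build_profile (scalar composition)
        and an independent re-transcription of the grading rules agree on
        2,000 randomized records."""
        rng = np.random.default_rng(42)
        df = random_records(2000, rng, refs)
        vec = score_cohort(df, refs)
        p85, p95, bpcuts = _vector_cutoffs(df, refs)
        for i in range(len(df)):
            row = df.iloc[i]
            rec = ParticipantRecord(**{k: row[k] for k in row.index})
            prof = build_profile(rec, refs)
            brute = _brute_force_statuses(row, (p85[i], p95[i]), bpcuts[i])
            for m in METRICS:
                assert vec[f"status_{m}"].iloc[i] == prof.statuses[m] == brute[m], (
                    f"row {i} metric {m}")
            assert vec["cvh_score"].iloc[i] == prof.cvh_score

    def test_monotonicity_worsening_inputs_never_raise_score(self, refs):
        """Raising TC/FBG/BP/BMI, cutting activity or failing a diet
        component can only leave the score unchanged or lower it."""
        rng = np.random.default_rng(7)
        df = random_records(400, rng, refs)
        base = score_cohort(df, refs)
        perturbations = {
            "tc_mgdl": 30.0, "fbg_mgdl": 27.0, "sbp": 12.0, "dbp": 8.0,
            "weight_kg": 8.0, "diet_ssb_per_week": 3.0,
        }
        for col, delta in perturbations.items():
            worse = df.copy()
            worse[col] = worse[col] + delta
            ws = score_cohort(worse, refs)
            assert (ws["cvh_score"] <= base["cvh_score"]).all(), col
        less_active = df.copy()
        less_active["mvpa_min_per_day"] = np.maximum(
            less_active["mvpa_min_per_day"] - 45, 0.0)
        assert (score_cohort(less_active, refs)["cvh_score"]
                <= base["cvh_score"]).all()


def _vector_cutoffs(df, refs):
    sex = df["sex"].to_numpy(object)
    age = df["age"].to_numpy(float)
    p85 = np.asarray(refs.bmi.value_at_percentile(sex, age, 85.0))
    p95 = np.asarray(refs.bmi.value_at_percentile(sex, age, 95.0))
    bp = [bp_cutoffs(refs, s, a, h)
          for s, a, h in zip(sex, age, df["height_cm"])]
    return p85, p95, bp


def _brute_force_statuses(row, bmi_cuts, bp_cuts):
    """Independent transcription of the grading table; deliberately
    written as literal if-chains, not shared with the implementation."""
    out = {}
    out["smoking"] = POOR if row["smoked_past_30d"] else IDEAL
    bmi = row["weight_kg"] / (row["height_cm"] / 100.0) ** 2
    p85, p95 = bmi_cuts
    if bmi > p95:
        out["bmi"] = POOR
    elif p85 <= bmi <= p95:
        out["bmi"] = INTERMEDIATE
    else:
        out["bmi"] = IDEAL
    m = row["mvpa_min_per_day"]
    out["physical_activity"] = POOR if m == 0 else (IDEAL if m >= 60
                                                    else INTERMEDIATE)
    count = 0
    count += 1 if row["diet_fruit_veg_per_day"] >= 1 else 0
    count += 1 if row["diet_aquatic_per_week"] >= 1 else 0
    count += 1 if row["diet_fried_fast_per_week"] <= 1 else 0
    count += 1 if row["diet_ssb_per_week"] < 1 else 0
    count += 1 if row["diet_bean_dairy_per_day"] >= 1 else 0
    out["diet"] = IDEAL if count >= 4 else (POOR if count <= 1 else INTERMEDIATE)
    tc = row["tc_mgdl"]
    out["total_cholesterol"] = POOR if tc >= 200 else (
        INTERMEDIATE if tc >= 170 else IDEAL)
    g = row["fbg_mgdl"]
    out["fasting_glucose"] = POOR if g >= 126 else (
        INTERMEDIATE if g >= 100 else IDEAL)
    s90, s95, d90, d95 = bp_cuts
    sbp, dbp = row["sbp"], row["dbp"]
    if sbp > s95 or dbp > d95:
        out["blood_pressure"] = POOR
    elif sbp >= s90 or dbp >= d90 or sbp >= 120 or dbp >= 80:
        out["blood_pressure"] = INTERMEDIATE
    else:
        out["blood_pressure"] = IDEAL
    return out


class TestDerivedCovariates:
    def test_passive_smoking_more_than_one_day(self):
        assert passive_smoking(2, False) is True
        assert passive_smoking(1, False) is False     # "more than 1" strict
        assert passive_smoking(0, True) is True
        assert passive_smoking(None, True) is True    # one True suffices
        assert passive_smoking(None, False) is None

    @pytest.mark.parametrize("bmi,expected", [
        (23.9, "normal"), (24.0, "overweight"), (27.9, "overweight"),
        (28.0, "obesity"), (None, None)])
    def test_parental_weight_bands(self, bmi, expected):
        assert parental_weight_status(bmi) == expected

    @pytest.mark.parametrize("age,hours,expected", [
        (12, 9.5, True),      # 6-12y band: 9-12 h
        (12, 8.5, False),
        (13, 8.5, True),      # 13-18y band: 8-10 h
        (13, 11.0, False),
        (6, 12.0, True),
    ])
    def test_sleep_adequacy_age_branches(self, age, hours, expected):
        assert sleep_adequate(age, hours) is expected

    def test_fmp_tertiles_within_wave(self, refs):
        rng = np.random.default_rng(3)
        df = random_records(600, rng, refs)
        cov = derive_covariates_frame(df)
        for year, g in cov.groupby(df["survey_year"]):
            counts = g["fmp_tertile"].value_counts()
            assert set(counts.index) <= {"T1", "T2", "T3"}
            # tertiles are near-balanced within each wave
            assert counts.max() - counts.min() <= 2
            t1 = g.loc[g["fmp_tertile"] == "T1", "fmp"].max()
            t3 = g.loc[g["fmp_tertile"] == "T3", "fmp"].min()
            assert t1 < t3

    def test_scalar_derivation_matches_frame(self, refs):
        rng = np.random.default_rng(9)
        df = random_records(50, rng, refs)
        cov = derive_covariates_frame(df)
        for i in range(len(df)):
            rec = ParticipantRecord(**{k: df.iloc[i][k] for k in df.columns})
            d = derive_covariates(rec)
            assert d.passive_smoking == cov["passive_smoking"].iloc[i]
            assert d.sedentary_flag == cov["sedentary_flag"].iloc[i]
            assert d.sleep_adequate == cov["sleep_adequate"].iloc[i]
            assert d.father_weight_status == cov["father_weight_status"].iloc[i]
            assert d.age_group == cov["age_group"].iloc[i]
            assert d.fmp == pytest.approx(cov["fmp"].iloc[i])


class TestUnits:
    def test_mmol_input_scores_identically(self, refs, tmp_path):
        rng = np.random.default_rng(11)
        df = random_records(80, rng, refs)
        mg = tmp_path / "mg.csv"
        mmol = tmp_path / "mmol.csv"
        df.to_csv(mg, index=False)
        df2 = df.copy()
        df2["tc_mgdl"] = df2["tc_mgdl"] / scoring.TC_MMOL_TO_MGDL
        df2["fbg_mgdl"] = df2["fbg_mgdl"] / scoring.GLUCOSE_MMOL_TO_MGDL
        df2.to_csv(mmol, index=False)
        a = score_cohort(scoring.load_participants(mg), refs)
        b = score_cohort(scoring.load_participants(
            mmol, units={"tc": "mmol/L", "fbg": "mmol/L"}), refs)
        assert (a["status_total_cholesterol"]
                == b["status_total_cholesterol"]).all()
        assert (a["status_fasting_glucose"] == b["status_fasting_glucose"]).all()
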