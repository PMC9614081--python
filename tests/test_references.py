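"""Reference-table loading, LMS machinery and percentile lookups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedcvh import tables
from pedcvh.references import (BPReference, LMSReference,
                               ReferenceValidationError, assign_height_band,
                               band_labels, bmi_cutoffs, bp_cutoffs,
                               lms_value, lms_zscore, load_reference_set)


class TestLMSFormula:
    def test_measurement_at_median_has_zero_zscore(self):
        for L in (-1.6, 0.0, 1.0, 2.3):
            assert lms_zscore(18.0, L, 18.0, 0.11) == pytest.approx(0.0)

    def test_l_equal_one_reduces_to_standardized_difference(self):
        # ((x/M)^1 - 1)/S = (x - M)/(M S)
        assert lms_zscore(19.8, 1.0, 18.0, 0.1) == pytest.approx(1.0)

    def test_l_zero_log_branch(self):
        assert lms_zscore(18.0 * np.exp(0.1), 0.0, 18.0, 0.1) == pytest.approx(1.0)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            lms_zscore(0.0, 1.0, 18.0, 0.1)

    def test_value_inverts_zscore(self):
        z = np.array([-2.0, -0.5, 0.0, 1.3, 2.5])
        for L in (-1.5, 0.0, 1.0):
            x = lms_value(z, L, 20.0, 0.1)
            np.testing.assert_allclose(lms_zscore(x, L, 20.0, 0.1), z, atol=1e-12)


class TestShippedTables:
    def test_data_files_match_builders(self, refs):
        """The TSVs shipped as package data are the frozen output of the
        synthetic table builders; a mismatch means corruption."""
        pd.testing.assert_frame_equal(
            refs.bmi.table.reset_index(drop=True), tables.synthetic_bmi_lms(),
            check_dtype=False)
        pd.testing.assert_frame_equal(
            refs.bp.table.reset_index(drop=True), tables.synthetic_bp_reference(),
            check_dtype=False)

    def test_round_trip_covers_both_sexes_and_cohort_ages(self, refs):
        for sex in ("male", "female"):
            lo, hi = refs.bmi.age_range(sex)
            assert lo <= 6.0 and hi >= 18.0
        assert set(refs.bp.ages) == set(range(6, 19))

    def test_bmi_cutoffs_nondecreasing_with_age(self, refs):
        """Guard against loader corruption: on the shipped tables the BMI
        p85/p95 cut-offs rise monotonically through childhood."""
        ages = np.arange(6.0, 18.01, 0.5)
        for sex in ("male", "female"):
            p85, p95 = bmi_cutoffs(refs, sex, ages)
            assert np.all(np.diff(p85) >= 0)
            assert np.all(np.diff(p95) >= 0)
            assert np.all(p85 < p95)


class TestValidation:
    def test_missing_column_named(self, tmp_path):
        bad = tables.synthetic_bmi_lms().drop(columns=["S"])
        p = tmp_path / "bmi.tsv"
        bad.to_csv(p, sep="\t", index=False)
        with pytest.raises(ReferenceValidationError, match="S"):
            LMSReference(pd.read_csv(p, sep="\t"), label=str(p))

    def test_zero_s_rejected(self):
        t = tables.synthetic_bmi_lms()
        t.loc[3, "S"] = 0.0
        with pytest.raises(ReferenceValidationError, match="S <= 0"):
            LMSReference(t)

    def test_non_monotone_age_grid_rejected(self):
        t = tables.synthetic_bmi_lms()
        t.loc[5, "age_years"] = t.loc[4, "age_years"]
        with pytest.raises(ReferenceValidationError, match="increasing"):
            LMSReference(t)

    def test_incomplete_bp_grid_names_cell(self):
        t = tables.synthetic_bp_reference()
        drop = (t["sex"].eq("female") & t["age_years"].eq(12)
                & t["height_band"].eq("P50-P75"))
        with pytest.raises(ReferenceValidationError, match="incomplete grid"):
            BPReference(t[~drop])

    def test_bp_p95_below_p90_rejected(self):
        t = tables.synthetic_bp_reference()
        t.loc[7, "sbp_p95"] = t.loc[7, "sbp_p90"] - 1
        with pytest.raises(ReferenceValidationError, match="sbp_p95"):
            BPReference(t)

    def test_full_set_loads_from_tsv(self, tmp_path):
        paths = tables.write_tables(tmp_path)
        rs = load_reference_set(paths["bmi_lms"], paths["bp_reference"],
                                paths["height_lms"])
        assert rs.bmi.age_range("male") == (6.0, 18.0)


class TestPercentileLookups:
    def test_median_returns_m_exactly_on_grid(self, refs):
        row = refs.bmi.table.query("sex == 'female' and age_years == 10.0").iloc[0]
        got = refs.bmi.value_at_percentile("female", 10.0, 50.0)
        assert got == pytest.approx(row["M"], abs=1e-12)

    def test_percentile_round_trip(self, refs):
        for p in (5.0, 25.0, 50.0, 85.0, 95.0, 99.0):
            x = refs.bmi.value_at_percentile("male", 11.25, p)
            assert refs.bmi.percentile_of("male", 11.25, x) == pytest.approx(
                p, abs=1e-9)

    def test_zscore_of_value_at_percentile_is_normal_quantile(self, refs):
        """Inverse property across a sex x age x percentile sweep."""
        ages = np.arange(6.0, 18.01, 1.5)
        ps = np.array([2.0, 15.0, 50.0, 85.0, 97.0])
        for sex in ("male", "female"):
            for p in ps:
                x = refs.bmi.value_at_percentile(sex, ages, p)
                z = refs.bmi.zscore(sex, ages, x)
                np.testing.assert_allclose(z, stats.norm.ppf(p / 100),
                                           atol=1e-9)

    def test_value_strictly_increasing_in_percentile(self, refs):
        ps = np.linspace(1, 99, 50)
        vals = [refs.bmi.value_at_percentile("female", 9.5, p) for p in ps]
        assert np.all(np.diff(vals) > 0)

    def test_age_interpolation_midway_uses_averaged_lms(self, refs):
        """At an age midway between grid points the cut-off equals the
        closed-form value from the arithmetic mean of L, M, S."""
        t = refs.bmi.table.query("sex == 'male'").reset_index(drop=True)
        a0 = t.loc[t["age_years"] == 9.0].iloc[0]
        a1 = t.loc[t["age_years"] == 9.5].iloc[0]
        L, M, S = [(a0[c] + a1[c]) / 2 for c in ("L", "M", "S")]
        z = stats.norm.ppf(0.85)
        expected = M * (1 + L * S * z) ** (1 / L)
        got = refs.bmi.value_at_percentile("male", 9.25, 85.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_age_outside_grid_is_hard_error(self, refs):
        with pytest.raises(ValueError, match="coverage"):
            refs.bmi.value_at_percentile("male", 5.0, 85.0)
        with pytest.raises(ValueError, match="coverage"):
            bmi_cutoffs(refs, "female", 18.5)


class TestCutoffs:
    def test_bmi_cutoffs_match_hand_inverse_lms(self, refs):
        row = refs.bmi.table.query("sex == 'female' and age_years == 10.0").iloc[0]
        L, M, S = row["L"], row["M"], row["S"]
        p85, p95 = bmi_cutoffs(refs, "female", 10.0)
        for p, got in ((0.85, p85), (0.95, p95)):
            assert got == pytest.approx(M * (1 + L * S * stats.norm.ppf(p)) ** (1 / L),
                                        rel=1e-12)
        assert p85 < p95

    def test_band_assignment_ties_go_up(self):
        labels = band_labels()
        assert assign_height_band(24.9) == labels[1]
        assert assign_height_band(25.0) == labels[2]   # edge -> upper band
        assert assign_height_band(4.99) == labels[0]
        assert assign_height_band(95.0) == labels[5]

    def test_bp_cutoffs_resolve_expected_cell(self, refs):
        """A boy exactly at the 50th height percentile lands in the
        P50-P75 band (left-closed intervals) of his completed age."""
        h50 = refs.height.value_at_percentile("male", 12.4, 50.0)
        cuts = bp_cutoffs(refs, "male", 12.4, h50)
        expected = refs.bp.cutoffs("male", 12, "P50-P75")
        assert cuts == expected
        assert cuts[1] >= cuts[0] and cuts[3] >= cuts[2]

    def test_bp_p95_ge_p90_everywhere(self, refs):
        t = refs.bp.table
        assert (t["sbp_p95"] >= t["sbp_p90"]).all()
        assert (t["dbp_p95"] >= t["dbp_p90"]).all()
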