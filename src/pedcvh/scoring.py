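"""Seven-metric cardiovascular-health classification and composite scores.

Each of the seven CVH metrics — four behaviors (smoking, BMI, physical
activity, diet) and three factors (blood pressure, total cholesterol,
fasting glucose) — is graded ``poor`` / ``intermediate`` / ``ideal``.
The composite CVH score counts ideal metrics (0–7); categories are poor
(0–2), intermediate (3–5) and ideal (6–7).  The behavior score counts
ideal behaviors (0–4, "ideal behaviors" when 3–4); the factor score counts
ideal factors (0–3, "ideal factors" only at 3).

Boundary conventions (documented, gapless over the reals):

* TC: ideal < 170 mg/dL, intermediate [170, 200), poor >= 200.
* FBG: ideal < 100 mg/dL, intermediate [100, 126), poor >= 126.
* BMI: ideal strictly below the 85th percentile; values exactly at the
  85th or 95th percentile are intermediate; poor strictly above the 95th.
* BP: poor strictly above the 95th percentile (either pressure);
  intermediate at/above the 90th percentile or at/above the absolute
  thresholds SBP 120 / DBP 80 mmHg; the worse pressure governs.
* MVPA: exactly 0 min/day is poor; (0, 60) intermediate; >= 60 ideal.
* Smoking is binary: poor if smoked in the prior 30 days, else ideal.

A record missing any metric input cannot be scored and is flagged invalid
rather than raising; covariate missingness is tolerated and handled
downstream by multiple imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

from .references import ReferenceSet, assign_height_band, bmi_cutoffs, bp_cutoffs

POOR, INTERMEDIATE, IDEAL = "poor", "intermediate", "ideal"
STATUSES = (POOR, INTERMEDIATE, IDEAL)

BEHAVIOR_METRICS = ("smoking", "bmi", "physical_activity", "diet")
FACTOR_METRICS = ("blood_pressure", "total_cholesterol", "fasting_glucose")
METRICS = BEHAVIOR_METRICS + FACTOR_METRICS

#: mg/dL per mmol/L
TC_MMOL_TO_MGDL = 38.67
GLUCOSE_MMOL_TO_MGDL = 18.016


@dataclass
class ParticipantRecord:
    """One child's raw survey measurements for one wave.

    Metric inputs use canonical units: cm, kg, mmHg, mg/dL, minutes/day.
    Any field may be ``None`` (missing); missing metric inputs make the
    record unscorable, missing covariates are imputed downstream.
    """

    id: object
    survey_year: int
    sex: str
    age: float
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    fat_mass_kg: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    tc_mgdl: Optional[float] = None
    fbg_mgdl: Optional[float] = None
    smoked_past_30d: Optional[bool] = None
    mvpa_min_per_day: Optional[float] = None
    diet_fruit_veg_per_day: Optional[float] = None
    diet_aquatic_per_week: Optional[float] = None
    diet_fried_fast_per_week: Optional[float] = None
    diet_ssb_per_week: Optional[float] = None
    diet_bean_dairy_per_day: Optional[float] = None
    sedentary_hours_per_day: Optional[float] = None
    sleep_hours_per_day: Optional[float] = None
    smoke_env_days_per_week: Optional[float] = None
    parent_current_smoker: Optional[bool] = None
    household_income: Optional[str] = None
    father_edu_college: Optional[bool] = None
    mother_edu_college: Optional[bool] = None
    father_bmi: Optional[float] = None
    mother_bmi: Optional[float] = None
    parental_cvd_history: Optional[bool] = None
    premature: Optional[bool] = None
    sexually_mature: Optional[bool] = None


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return False


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index: weight (kg) / height (m) squared."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def classify_smoking(smoked_past_30d) -> Optional[str]:
    """Poor if smoked in the prior 30 days, ideal otherwise (no
    intermediate level exists for smoking)."""
    if _is_missing(smoked_past_30d):
        return None
    return POOR if smoked_past_30d else IDEAL


def classify_bmi(bmi, p85, p95) -> Optional[str]:
    if _is_missing(bmi):
        return None
    if bmi > p95:
        return POOR
    if bmi >= p85:
        return INTERMEDIATE
    return IDEAL


def classify_physical_activity(mvpa_min_per_day) -> Optional[str]:
    if _is_missing(mvpa_min_per_day):
        return None
    if mvpa_min_per_day < 0:
        raise ValueError("MVPA minutes must be non-negative")
    if mvpa_min_per_day == 0:
        return POOR
    if mvpa_min_per_day < 60:
        return INTERMEDIATE
    return IDEAL


def score_diet_components(fruit_veg_per_day, aquatic_per_week,
                          fried_fast_per_week, ssb_per_week,
                          bean_dairy_per_day) -> Optional[int]:
    """Count of satisfied healthy-diet components (0–5).

    Components: fruits/vegetables >= 1/day; aquatic foods >= 1/week;
    fried or fast food <= 1/week (inclusive); sugar-sweetened beverages
    < 1/week (strict); bean-curd or dairy >= 1/day.
    """
    answers = (fruit_veg_per_day, aquatic_per_week, fried_fast_per_week,
               ssb_per_week, bean_dairy_per_day)
    if any(_is_missing(a) for a in answers):
        return None
    satisfied = (
        fruit_veg_per_day >= 1,
        aquatic_per_week >= 1,
        fried_fast_per_week <= 1,
        ssb_per_week < 1,
        bean_dairy_per_day >= 1,
    )
    return sum(bool(s) for s in satisfied)


def classify_diet(component_count) -> Optional[str]:
    if _is_missing(component_count):
        return None
    if component_count not in (0, 1, 2, 3, 4, 5):
        raise ValueError("diet component count must be an integer in 0–5")
    if component_count >= 4:
        return IDEAL
    if component_count >= 2:
        return INTERMEDIATE
    return POOR


def classify_tc(tc_mgdl) -> Optional[str]:
    if _is_missing(tc_mgdl):
        return None
    if tc_mgdl <= 0:
        raise ValueError("total cholesterol must be positive")
    if tc_mgdl >= 200:
        return POOR
    if tc_mgdl >= 170:
        return INTERMEDIATE
    return IDEAL


def classify_fbg(fbg_mgdl) -> Optional[str]:
    if _is_missing(fbg_mgdl):
        return None
    if fbg_mgdl <= 0:
        raise ValueError("fasting glucose must be positive")
    if fbg_mgdl >= 126:
        return POOR
    if fbg_mgdl >= 100:
        return INTERMEDIATE
    return IDEAL


def classify_bp(sbp, dbp, cutoffs) -> Optional[str]:
    """Classify averaged untreated BP against percentile ``cutoffs`` =
    (sbp_p90, sbp_p95, dbp_p90, dbp_p95); the worse pressure governs and
    the absolute SBP>=120 / DBP>=80 rule can only worsen ideal to
    intermediate."""
    if _is_missing(sbp) or _is_missing(dbp):
        return None
    sbp_p90, sbp_p95, dbp_p90, dbp_p95 = cutoffs
    if sbp > sbp_p95 or dbp > dbp_p95:
        return POOR
    if sbp >= sbp_p90 or dbp >= dbp_p90 or sbp >= 120 or dbp >= 80:
        return INTERMEDIATE
    return IDEAL


@dataclass
class CVHProfile:
    """Per-metric statuses plus composite scores for one participant."""

    id: object
    statuses: dict
    diet_component_count: Optional[int]
    valid: bool
    missing_metrics: tuple = ()
    cvh_score: Optional[int] = None
    behavior_score: Optional[int] = None
    factor_score: Optional[int] = None
    cvh_category: Optional[str] = None
    ideal_behaviors: Optional[bool] = None
    ideal_factors: Optional[bool] = None


def cvh_category(score: int) -> str:
    """CVH category from the 0–7 score: poor 0–2, intermediate 3–5,
    ideal 6–7."""
    if score >= 6:
        return IDEAL
    if score >= 3:
        return INTERMEDIATE
    return POOR


def profile_from_statuses(pid, statuses: dict, diet_count=None) -> CVHProfile:
    """Assemble the composite scores from seven per-metric statuses."""
    missing = tuple(m for m in METRICS if _is_missing(statuses.get(m)))
    if missing:
        return CVHProfile(id=pid, statuses=statuses,
                          diet_component_count=diet_count,
                          valid=False, missing_metrics=missing)
    behavior = sum(statuses[m] == IDEAL for m in BEHAVIOR_METRICS)
    factor = sum(statuses[m] == IDEAL for m in FACTOR_METRICS)
    score = behavior + factor
    return CVHProfile(
        id=pid, statuses=dict(statuses), diet_component_count=diet_count,
        valid=True, cvh_score=score, behavior_score=behavior,
        factor_score=factor, cvh_category=cvh_category(score),
        ideal_behaviors=behavior >= 3, ideal_factors=factor == 3,
    )


def build_profile(record: ParticipantRecord, refs: ReferenceSet) -> CVHProfile:
    """Classify all seven metrics for one record and compose the scores.

    Records missing any metric input come back with ``valid=False`` and
    the offending metrics listed, mirroring the exclusion of participants
    without complete CVH metric data.
    """
    statuses = {}
    statuses["smoking"] = classify_smoking(record.smoked_past_30d)

    if any(_is_missing(v) for v in (record.weight_kg, record.height_cm)):
        statuses["bmi"] = None
    else:
        bmi = compute_bmi(record.weight_kg, record.height_cm)
        p85, p95 = bmi_cutoffs(refs, record.sex, record.age)
        statuses["bmi"] = classify_bmi(bmi, p85, p95)

    statuses["physical_activity"] = classify_physical_activity(record.mvpa_min_per_day)

    diet_count = score_diet_components(
        record.diet_fruit_veg_per_day, record.diet_aquatic_per_week,
        record.diet_fried_fast_per_week, record.diet_ssb_per_week,
        record.diet_bean_dairy_per_day)
    statuses["diet"] = classify_diet(diet_count)

    if any(_is_missing(v) for v in (record.sbp, record.dbp, record.height_cm)):
        statuses["blood_pressure"] = None
    else:
        cuts = bp_cutoffs(refs, record.sex, record.age, record.height_cm)
        statuses["blood_pressure"] = classify_bp(record.sbp, record.dbp, cuts)

    statuses["total_cholesterol"] = classify_tc(record.tc_mgdl)
    statuses["fasting_glucose"] = classify_fbg(record.fbg_mgdl)

    return profile_from_statuses(record.id, statuses, diet_count)


# ---------------------------------------------------------------------------
# Vectorized cohort path
# ---------------------------------------------------------------------------

def score_cohort(df: pd.DataFrame, refs: ReferenceSet) -> pd.DataFrame:
    """Score a whole participant table at once.

    Returns a frame indexed like ``df`` with the seven ``status_*``
    columns, ``diet_components``, composite scores/categories, a ``valid``
    flag and a ``missing_metrics`` reason string.  Semantics match
    :func:`build_profile` row for row.
    """
    n = len(df)
    out = pd.DataFrame(index=df.index)
    sex = df["sex"].to_numpy(dtype=object)
    age = df["age"].to_numpy(dtype=float)

    def col(name):
        return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)

    # smoking
    smoked = df["smoked_past_30d"]
    smoked_num = pd.to_numeric(smoked, errors="coerce").to_numpy(dtype=float)
    out["status_smoking"] = np.where(
        np.isnan(smoked_num), None, np.where(smoked_num > 0, POOR, IDEAL))

    # BMI
    height = col("height_cm")
    weight = col("weight_kg")
    bmi = np.full(n, np.nan)
    ok = ~np.isnan(height) & ~np.isnan(weight)
    bmi[ok] = weight[ok] / (height[ok] / 100.0) ** 2
    p85 = np.asarray(refs.bmi.value_at_percentile(sex, age, 85.0), dtype=float)
    p95 = np.asarray(refs.bmi.value_at_percentile(sex, age, 95.0), dtype=float)
    out["bmi"] = bmi
    out["status_bmi"] = _band_status(bmi, p85, p95, low_inclusive=True)

    # physical activity
    mvpa = col("mvpa_min_per_day")
    if np.any(mvpa[~np.isnan(mvpa)] < 0):
        raise ValueError("MVPA minutes must be non-negative")
    out["status_physical_activity"] = np.select(
        [np.isnan(mvpa), mvpa == 0, mvpa < 60],
        [None, POOR, INTERMEDIATE], default=IDEAL)

    # diet
    fv = col("diet_fruit_veg_per_day")
    aq = col("diet_aquatic_per_week")
    fr = col("diet_fried_fast_per_week")
    ssb = col("diet_ssb_per_week")
    bd = col("diet_bean_dairy_per_day")
    diet_missing = np.isnan(fv) | np.isnan(aq) | np.isnan(fr) | np.isnan(ssb) | np.isnan(bd)
    count = ((fv >= 1).astype(float) + (aq >= 1) + (fr <= 1)
             + (ssb < 1) + (bd >= 1))
    count[diet_missing] = np.nan
    out["diet_components"] = count
    out["status_diet"] = np.select(
        [diet_missing, count >= 4, count >= 2], [None, IDEAL, INTERMEDIATE],
        default=POOR)

    # blood pressure
    sbp = col("sbp")
    dbp = col("dbp")
    bp_missing = np.isnan(sbp) | np.isnan(dbp) | np.isnan(height)
    cuts = np.full((n, 4), np.nan)
    if (~bp_missing).any():
        idx = ~bp_missing
        pct = 100.0 * _norm_cdf(np.asarray(
            refs.height.zscore(sex[idx], age[idx], height[idx]), dtype=float))
        bands = assign_height_band(pct, refs.bp.band_edges)
        key = pd.DataFrame({
            "sex": sex[idx], "age_years": np.floor(age[idx]).astype(int),
            "height_band": bands})
        merged = key.merge(refs.bp.table, on=["sex", "age_years", "height_band"],
                           how="left", validate="many_to_one")
        cuts[idx] = merged[["sbp_p90", "sbp_p95", "dbp_p90", "dbp_p95"]].to_numpy()
    poor_bp = (sbp > cuts[:, 1]) | (dbp > cuts[:, 3])
    inter_bp = (sbp >= cuts[:, 0]) | (dbp >= cuts[:, 2]) | (sbp >= 120) | (dbp >= 80)
    out["status_blood_pressure"] = np.select(
        [bp_missing, poor_bp, inter_bp], [None, POOR, INTERMEDIATE], default=IDEAL)

    # lipids / glucose
    tc = col("tc_mgdl")
    if np.any(tc[~np.isnan(tc)] <= 0):
        raise ValueError("total cholesterol must be positive")
    out["status_total_cholesterol"] = np.select(
        [np.isnan(tc), tc >= 200, tc >= 170], [None, POOR, INTERMEDIATE],
        default=IDEAL)
    fbg = col("fbg_mgdl")
    if np.any(fbg[~np.isnan(fbg)] <= 0):
        raise ValueError("fasting glucose must be positive")
    out["status_fasting_glucose"] = np.select(
        [np.isnan(fbg), fbg >= 126, fbg >= 100], [None, POOR, INTERMEDIATE],
        default=IDEAL)

    status_cols = [f"status_{m}" for m in METRICS]
    statuses = out[status_cols]
    valid = statuses.notna().all(axis=1)
    out["valid"] = valid
    out["missing_metrics"] = [
        ",".join(m for m, s in zip(METRICS, row) if s is None)
        for row in statuses.to_numpy()
    ]
    ideal_mat = (statuses == IDEAL)
    behavior = ideal_mat[[f"status_{m}" for m in BEHAVIOR_METRICS]].sum(axis=1)
    factor = ideal_mat[[f"status_{m}" for m in FACTOR_METRICS]].sum(axis=1)
    score = behavior + factor
    out["behavior_score"] = behavior.where(valid)
    out["factor_score"] = factor.where(valid)
    out["cvh_score"] = score.where(valid)
    out["cvh_category"] = pd.Series(
        np.select([score >= 6, score >= 3], [IDEAL, INTERMEDIATE], default=POOR),
        index=df.index).where(valid)
    out["ideal_behaviors"] = (behavior >= 3).where(valid)
    out["ideal_factors"] = (factor == 3).where(valid)
    return out


def _band_status(value, low_cut, high_cut, low_inclusive=True):
    """Three-band status where poor is strictly above ``high_cut`` and
    values at either cut-off are intermediate."""
    value = np.asarray(value, dtype=float)
    return np.select(
        [np.isnan(value), value > high_cut, value >= low_cut],
        [None, POOR, INTERMEDIATE], default=IDEAL)


def _norm_cdf(z):
    from scipy.special import ndtr

    return ndtr(z)


# ---------------------------------------------------------------------------
# Derived questionnaire covariates
# ---------------------------------------------------------------------------

PARENT_BMI_NORMAL_MAX = 24.0   # kg/m^2, exclusive upper bound of "normal"
PARENT_BMI_OBESE_MIN = 28.0    # kg/m^2, inclusive lower bound of "obesity"


def parental_weight_status(bmi) -> Optional[str]:
    """normal < 24, overweight 24–<28, obesity >= 28 kg/m^2."""
    if _is_missing(bmi):
        return None
    if bmi >= PARENT_BMI_OBESE_MIN:
        return "obesity"
    if bmi >= PARENT_BMI_NORMAL_MAX:
        return "overweight"
    return "normal"


def sleep_adequate(age, sleep_hours) -> Optional[bool]:
    """Adequate sleep: 9–12 h/day at ages 6–12, 8–10 h/day at 13–18
    (completed years; age 12 uses the younger band)."""
    if _is_missing(sleep_hours):
        return None
    if math.floor(age) <= 12:
        return 9.0 <= sleep_hours <= 12.0
    return 8.0 <= sleep_hours <= 10.0


def passive_smoking(smoke_env_days_per_week, parent_current_smoker) -> Optional[bool]:
    """Exposed if in a smoking environment more than 1 day/week or a
    parent currently smokes.  A single True suffices even when the other
    answer is missing; both must be non-missing to return False."""
    env_missing = _is_missing(smoke_env_days_per_week)
    par_missing = _is_missing(parent_current_smoker)
    env = (not env_missing) and smoke_env_days_per_week > 1
    par = (not par_missing) and bool(parent_current_smoker)
    if env or par:
        return True
    if env_missing or par_missing:
        return None
    return False


def age_group(age) -> str:
    return "6-11" if math.floor(age) <= 11 else "12-18"


def derive_covariates_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized derivation of questionnaire covariates for a cohort.

    Fat-mass percentage tertiles are computed within each survey wave
    because body-composition devices differ across waves; pooling would
    change what a tertile means.
    """
    out = pd.DataFrame(index=df.index)
    num = lambda c: pd.to_numeric(df[c], errors="coerce")

    env = num("smoke_env_days_per_week")
    par = pd.to_numeric(df["parent_current_smoker"], errors="coerce")
    exposed = (env > 1) | (par > 0)
    known = env.notna() & par.notna()
    out["passive_smoking"] = exposed.where(exposed | known)

    sed = num("sedentary_hours_per_day")
    out["sedentary_flag"] = (sed >= 2).where(sed.notna())

    sleep = num("sleep_hours_per_day")
    young = np.floor(num("age")) <= 12
    adequate = np.where(young, (sleep >= 9) & (sleep <= 12),
                        (sleep >= 8) & (sleep <= 10))
    out["sleep_adequate"] = pd.Series(adequate, index=df.index).where(sleep.notna())

    for parent in ("father", "mother"):
        b = num(f"{parent}_bmi")
        out[f"{parent}_weight_status"] = pd.Series(
            np.select([b >= PARENT_BMI_OBESE_MIN, b >= PARENT_BMI_NORMAL_MAX],
                      ["obesity", "overweight"], default="normal"),
            index=df.index).where(b.notna())

    out["age_group"] = np.where(np.floor(num("age")) <= 11, "6-11", "12-18")

    fat = num("fat_mass_kg")
    weight = num("weight_kg")
    fmp = 100.0 * fat / weight
    out["fmp"] = fmp
    tert = pd.Series(pd.NA, index=df.index, dtype=object)
    for _, idx in df.groupby("survey_year").groups.items():
        vals = fmp.loc[idx]
        obs = vals.dropna()
        if len(obs) >= 3:
            q1, q2 = obs.quantile([1 / 3, 2 / 3])
            tert.loc[idx] = pd.Series(
                np.select([vals.loc[idx] <= q1, vals.loc[idx] <= q2],
                          ["T1", "T2"], default="T3"),
                index=idx).where(vals.loc[idx].notna())
    out["fmp_tertile"] = tert
    return out


@dataclass
class DerivedCovariates:
    """Scalar bundle of derived covariates for one record."""

    bmi: Optional[float]
    fmp: Optional[float]
    passive_smoking: Optional[bool]
    sedentary_flag: Optional[bool]
    sleep_adequate: Optional[bool]
    father_weight_status: Optional[str]
    mother_weight_status: Optional[str]
    age_group: str
    fmp_tertile: Optional[str] = None


def derive_covariates(record: ParticipantRecord,
                      fmp_tertile_cutoffs=None) -> DerivedCovariates:
    """Scalar counterpart of :func:`derive_covariates_frame`.

    ``fmp_tertile_cutoffs`` is the within-wave (q1, q2) pair; without it
    the tertile is left unset (it is a cohort-level quantity).
    """
    bmi = None
    if not (_is_missing(record.weight_kg) or _is_missing(record.height_cm)):
        bmi = compute_bmi(record.weight_kg, record.height_cm)
    fmp = None
    if not (_is_missing(record.fat_mass_kg) or _is_missing(record.weight_kg)):
        fmp = 100.0 * record.fat_mass_kg / record.weight_kg
    tert = None
    if fmp is not None and fmp_tertile_cutoffs is not None:
        q1, q2 = fmp_tertile_cutoffs
        tert = "T1" if fmp <= q1 else ("T2" if fmp <= q2 else "T3")
    sleep = None if _is_missing(record.sleep_hours_per_day) else sleep_adequate(
        record.age, record.sleep_hours_per_day)
    sed = None if _is_missing(record.sedentary_hours_per_day) else (
        record.sedentary_hours_per_day >= 2)
    return DerivedCovariates(
        bmi=bmi, fmp=fmp,
        passive_smoking=passive_smoking(record.smoke_env_days_per_week,
                                        record.parent_current_smoker),
        sedentary_flag=sed, sleep_adequate=sleep,
        father_weight_status=parental_weight_status(record.father_bmi),
        mother_weight_status=parental_weight_status(record.mother_bmi),
        age_group=age_group(record.age), fmp_tertile=tert,
    )


# ---------------------------------------------------------------------------
# Participant CSV I/O
# ---------------------------------------------------------------------------

BOOL_COLUMNS = ("smoked_past_30d", "parent_current_smoker",
                "father_edu_college", "mother_edu_college",
                "parental_cvd_history", "premature", "sexually_mature")


def load_participants(path, units: dict | None = None) -> pd.DataFrame:
    """Read a participant CSV, converting declared units to canonical
    mg/dL.  ``units`` maps ``tc`` / ``fbg`` to ``"mg/dL"`` or ``"mmol/L"``
    (the sidecar schema); omitted keys default to mg/dL."""
    df = pd.read_csv(path)
    units = units or {}
    factors = {"tc": ("tc_mgdl", TC_MMOL_TO_MGDL),
               "fbg": ("fbg_mgdl", GLUCOSE_MMOL_TO_MGDL)}
    for key, (colname, factor) in factors.items():
        unit = units.get(key, "mg/dL")
        if unit not in ("mg/dL", "mmol/L"):
            raise ValueError(f"unknown unit {unit!r} for {key}")
        if unit == "mmol/L":
            df[colname] = pd.to_numeric(df[colname], errors="coerce") * factor
    return df
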