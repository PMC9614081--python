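import numpy as np
import pandas as pd
import pytest

from pedcvh import references
from pedcvh.cohort import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def refs():
    return references.default_reference_set()


@pytest.fixture(scope="session")
def small_cohort(refs):
    """One deterministic three-wave cohort shared by read-only tests."""
    spec = default_cohort_spec(n_per_wave=800)
    return generate_cohort(spec, seed=1234, refs=refs, with_missingness=False)


def random_records(n, rng, refs):
    """Randomized metric-complete participant rows spanning the
    classification boundaries (uniform draws around every threshold)."""
    sex = np.where(rng.random(n) < 0.5, "male", "female").astype(object)
    age = rng.uniform(6.0, 17.99, n)
    height = np.asarray(refs.height.value_at_percentile(
        sex, age, np.clip(rng.uniform(1, 99, n), 1, 99)))
    bmi = np.asarray(refs.bmi.value_at_percentile(
        sex, age, np.clip(rng.uniform(1, 99.9, n), 1, 99.9)))
    weight = bmi * (height / 100) ** 2
    return pd.DataFrame({
        "id": np.arange(n),
        "survey_year": rng.choice([2004, 2014, 2019], n),
        "sex": sex,
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "fat_mass_kg": weight * rng.uniform(0.08, 0.45, n),
        "sbp": rng.uniform(85, 135, n),
        "dbp": rng.uniform(50, 85, n),
        "tc_mgdl": rng.uniform(120, 240, n),
        "fbg_mgdl": rng.uniform(70, 140, n),
        "smoked_past_30d": rng.integers(0, 2, n),
        "mvpa_min_per_day": np.where(rng.random(n) < 0.15, 0.0,
                                     rng.uniform(0, 150, n)),
        "diet_fruit_veg_per_day": rng.uniform(0, 3, n),
        "diet_aquatic_per_week": rng.uniform(0, 4, n),
        "diet_fried_fast_per_week": rng.uniform(0, 4, n),
        "diet_ssb_per_week": rng.uniform(0, 4, n),
        "diet_bean_dairy_per_day": rng.uniform(0, 3, n),
        "sedentary_hours_per_day": rng.uniform(0, 8, n),
        "sleep_hours_per_day": rng.uniform(5, 13, n),
        "smoke_env_days_per_week": rng.integers(0, 8, n),
        "parent_current_smoker": rng.integers(0, 2, n),
        "household_income": rng.choice(["poor", "middle", "high"], n),
        "father_edu_college": rng.integers(0, 2, n),
        "mother_edu_college": rng.integers(0, 2, n),
        "father_bmi": rng.uniform(18, 35, n),
        "mother_bmi": rng.uniform(17, 34, n),
        "parental_cvd_history": rng.integers(0, 2, n),
        "premature": rng.integers(0, 2, n),
        "sexually_mature": rng.integers(0, 2, n),
    })
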