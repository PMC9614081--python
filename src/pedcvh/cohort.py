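"""Synthetic three-wave cohort generator.

The survey data behind multi-wave pediatric CVH analyses are typically
not deposited, so this module generates cohorts with the statistical
structure such an analysis assumes: three cross-sectional waves (2004,
2014, 2019) of children aged 6–18 with sex structure, correlated
anthropometry/BP/body-fat through a shared adiposity latent, correlated
lifestyle behaviors (diet, activity, sedentary time) through a lifestyle
latent, wave-specific marginal prevalences, and MAR covariate
missingness.

Marginal control is exact where a closed form exists: metric inputs are
drawn through the same reference tables the scorer classifies against, so
e.g. the probability of ideal BMI equals the configured target by
construction.  Blood pressure additionally faces the absolute
SBP>=120/DBP>=80 rule, so its wave-level location shift is calibrated
once (large-sample Monte Carlo, frozen in the presets) to hit the
configured ideal-BP target.

Wave presets are calibrated *qualitatively* to the published wave
marginals of a Beijing school survey series (direction and approximate
level per metric); no preset output reproduces any actual survey
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .references import ReferenceSet, assign_height_band, default_reference_set

__all__ = [
    "WaveSpec",
    "CohortSpec",
    "MissingnessSpec",
    "GeneratedCohort",
    "wave_presets",
    "default_cohort_spec",
    "generate_cohort",
    "generate_wave",
    "inject_missingness",
    "diet_band_probs",
    "logistic_mar_benchmark",
]

_EPS = 1e-9
_Z85, _Z95 = stats.norm.ppf([0.85, 0.95])
_Z90BP, _Z95BP = stats.norm.ppf([0.90, 0.95])

#: questionnaire/parental covariates eligible for MAR blanking; the seven
#: metric inputs are never blanked.
COVARIATE_COLUMNS = (
    "fat_mass_kg", "smoke_env_days_per_week", "parent_current_smoker",
    "household_income", "father_edu_college", "mother_edu_college",
    "father_bmi", "mother_bmi", "parental_cvd_history", "premature",
    "sexually_mature", "sedentary_hours_per_day", "sleep_hours_per_day",
)


def _ppf(p):
    return stats.norm.ppf(np.clip(p, _EPS, 1 - _EPS))


def _solve_band_normal(p_ideal: float, p_poor: float,
                       z_low: float, z_high: float) -> tuple[float, float]:
    """Mean/SD of a latent normal so that P(z < z_low) = p_ideal and
    P(z > z_high) = p_poor."""
    a = _ppf(p_ideal)
    b = _ppf(1.0 - p_poor)
    if b - a < 1e-6:
        return z_low - a, 1.0
    sd = (z_high - z_low) / (b - a)
    return z_low - a * sd, sd


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def diet_band_probs(component_probs, loading: float) -> tuple[float, float, float]:
    """(poor, intermediate, ideal) diet-band probabilities implied by the
    latent-factor model: component j is satisfied iff a standard-normal
    score with correlation ``loading`` to the shared healthy-eater latent
    falls below the per-component threshold.  Computed by Gauss–Hermite
    quadrature over the latent."""
    probs = np.asarray(component_probs, dtype=float)
    thr = _ppf(probs)
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    w = weights / weights.sum()
    denom = np.sqrt(max(1.0 - loading**2, 1e-12))
    # P(component satisfied | latent = node)
    p_cond = stats.norm.cdf((thr[None, :] - loading * nodes[:, None]) / denom)
    # Poisson-binomial over the 5 components at each node
    count_pmf = np.zeros((len(nodes), len(probs) + 1))
    count_pmf[:, 0] = 1.0
    for j in range(len(probs)):
        pj = p_cond[:, j][:, None]
        new = np.zeros_like(count_pmf)
        new[:, 1:] = count_pmf[:, :-1] * pj
        new += count_pmf * (1 - pj)
        count_pmf = new
    pmf = (count_pmf * w[:, None]).sum(axis=0)
    return float(pmf[:2].sum()), float(pmf[2:4].sum()), float(pmf[4:].sum())


@dataclass(frozen=True)
class WaveSpec:
    """Parameterization of one synthetic survey wave.

    Per-sex marginals are dicts keyed ``male``/``female``; BMI and PA use
    (ideal, poor) band targets that are inverted into latent normal
    parameters at generation time, so the configured targets hold exactly
    under the scorer's own reference tables.
    """

    year: int
    boys_fraction: float
    smoking_poor: dict
    bmi_ideal: dict
    bmi_poor: dict
    pa_poor: dict
    pa_ideal: dict
    diet_component_probs: tuple
    tc_mean: float     # mg/dL
    tc_sd: float
    fbg_mean: float    # mg/dL
    fbg_sd: float
    bp_shift: float            # latent SD units; calibrated
    bp_ideal_target: float     # implied ideal-BP fraction at calibration
    # latent structure
    adiposity_bmi_loading: float = 0.70
    bp_adiposity_loading: float = 0.45
    metabolic_adiposity_loading: float = 0.25
    bp_pressure_share: float = 0.85
    lifestyle_pa_loading: float = 0.50
    diet_loading: float = 0.50
    pa_sigma_log: float = 0.80
    # body fat
    fmp_base: float = 18.0
    fmp_female_offset: float = 3.0
    fmp_age_slope: float = 0.15
    fmp_adiposity_slope: float = 4.0
    fmp_noise_sd: float = 3.0
    # covariates
    income_probs: tuple = (0.06, 0.22, 0.72)     # poor, middle, high
    father_edu_college: float = 0.3
    mother_edu_college: float = 0.3
    father_bmi_bands: tuple = (0.48, 0.11)       # (P(normal), P(obese))
    mother_bmi_bands: tuple = (0.65, 0.07)
    parental_cvd: float = 0.14
    parent_smoker: float = 0.5
    smoke_env_gt1: float = 0.33
    sedentary_ge2h: float = 0.44
    sleep_adequate_p: float = 0.69
    premature_p: float = 0.046
    age_low: float = 6.0
    age_high: float = 18.0

    def _sex_weights(self):
        return {"male": self.boys_fraction, "female": 1.0 - self.boys_fraction}

    def implied_ideal_targets(self) -> dict:
        """Ideal-level marginal target for each of the 7 metrics.

        Exact for smoking/BMI/PA/TC/FBG (closed form) and diet
        (quadrature); blood pressure reports the calibrated target."""
        w = self._sex_weights()
        smoking = sum(w[s] * (1.0 - self.smoking_poor[s]) for s in w)
        bmi = sum(w[s] * self.bmi_ideal[s] for s in w)
        pa = sum(w[s] * self.pa_ideal[s] for s in w)
        _, _, diet = diet_band_probs(self.diet_component_probs, self.diet_loading)
        mu, sigma = _lognormal_params(self.tc_mean, self.tc_sd)
        tc = float(stats.norm.cdf((np.log(170.0) - mu) / sigma))
        fbg = float(stats.norm.cdf((100.0 - self.fbg_mean) / self.fbg_sd))
        return {
            "smoking": smoking, "bmi": bmi, "physical_activity": pa,
            "diet": diet, "total_cholesterol": tc, "fasting_glucose": fbg,
            "blood_pressure": self.bp_ideal_target,
        }


@dataclass(frozen=True)
class MissingnessSpec:
    """MAR covariate missingness: per-covariate blanking probability on
    the logit scale depends on observed wave and sex; the base rate is
    solved so the expected fraction of records with >= 1 missing
    covariate equals ``overall_target``."""

    overall_target: float = 0.32
    wave_logit: dict = field(default_factory=lambda: {2004: 0.25, 2014: 0.0,
                                                      2019: -0.25})
    sex_logit: dict = field(default_factory=lambda: {"male": 0.15,
                                                     "female": -0.15})
    columns: tuple = COVARIATE_COLUMNS

    def __post_init__(self):
        if not 0.0 <= self.overall_target < 1.0:
            raise ValueError("overall_target must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of the synthetic multi-wave generator."""

    waves: dict                      # year -> WaveSpec
    n_per_wave: dict                 # year -> int
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)

    def __post_init__(self):
        for year, n in self.n_per_wave.items():
            if year not in self.waves:
                raise ValueError(f"no WaveSpec for year {year}")
            if n <= 0:
                raise ValueError(f"n for wave {year} must be positive")


@dataclass
class GeneratedCohort:
    records: pd.DataFrame
    truth: pd.DataFrame              # per-record latents for recovery tests
    spec: CohortSpec
    seed: int


def wave_presets() -> dict:
    """The three default wave parameterizations.

    Marginal targets follow the published wave-level direction per metric
    (e.g. ideal BMI monotone decreasing 2004->2019; ideal PA lowest in
    2014); BP shifts were calibrated by large-sample Monte Carlo against
    the shipped reference tables.
    """
    return {
        2004: WaveSpec(
            year=2004, boys_fraction=0.495,
            smoking_poor={"male": 0.037, "female": 0.013},
            bmi_ideal={"male": 0.726, "female": 0.823},
            bmi_poor={"male": 0.133, "female": 0.079},
            pa_poor={"male": 0.094, "female": 0.147},
            pa_ideal={"male": 0.300, "female": 0.251},
            diet_component_probs=(0.92, 0.33, 0.55, 0.40, 0.44),
            tc_mean=154.7, tc_sd=13.5, fbg_mean=83.2, fbg_sd=9.4,
            bp_shift=0.3807, bp_ideal_target=0.736,
            fmp_base=17.0,
            income_probs=(0.058, 0.215, 0.727),
            father_edu_college=0.296, mother_edu_college=0.288,
            father_bmi_bands=(0.482, 0.108), mother_bmi_bands=(0.655, 0.070),
            parental_cvd=0.137, parent_smoker=0.50, smoke_env_gt1=0.33,
            sedentary_ge2h=0.444, sleep_adequate_p=0.694, premature_p=0.046,
        ),
        2014: WaveSpec(
            year=2014, boys_fraction=0.553,
            smoking_poor={"male": 0.096, "female": 0.039},
            bmi_ideal={"male": 0.531, "female": 0.737},
            bmi_poor={"male": 0.248, "female": 0.118},
            pa_poor={"male": 0.189, "female": 0.249},
            pa_ideal={"male": 0.175, "female": 0.106},
            diet_component_probs=(0.90, 0.15, 0.45, 0.33, 0.20),
            tc_mean=163.6, tc_sd=27.5, fbg_mean=100.9, fbg_sd=9.7,
            bp_shift=0.5018, bp_ideal_target=0.693,
            fmp_base=27.0,
            income_probs=(0.033, 0.157, 0.810),
            father_edu_college=0.848, mother_edu_college=0.793,
            father_bmi_bands=(0.364, 0.138), mother_bmi_bands=(0.730, 0.050),
            parental_cvd=0.214, parent_smoker=0.35, smoke_env_gt1=0.20,
            sedentary_ge2h=0.271, sleep_adequate_p=0.767, premature_p=0.044,
        ),
        2019: WaveSpec(
            year=2019, boys_fraction=0.497,
            smoking_poor={"male": 0.035, "female": 0.006},
            bmi_ideal={"male": 0.518, "female": 0.674},
            bmi_poor={"male": 0.274, "female": 0.165},
            pa_poor={"male": 0.050, "female": 0.038},
            pa_ideal={"male": 0.291, "female": 0.269},
            diet_component_probs=(0.50, 0.25, 0.70, 0.56, 0.42),
            tc_mean=155.8, tc_sd=29.0, fbg_mean=92.6, fbg_sd=7.4,
            bp_shift=0.5563, bp_ideal_target=0.673,
            fmp_base=23.0,
            income_probs=(0.050, 0.392, 0.558),
            father_edu_college=0.558, mother_edu_college=0.592,
            father_bmi_bands=(0.314, 0.248), mother_bmi_bands=(0.610, 0.134),
            parental_cvd=0.267, parent_smoker=0.22, smoke_env_gt1=0.14,
            sedentary_ge2h=0.072, sleep_adequate_p=0.554, premature_p=0.057,
        ),
    }


def default_cohort_spec(n_per_wave=5000,
                        missingness: MissingnessSpec | None = None) -> CohortSpec:
    waves = wave_presets()
    if isinstance(n_per_wave, int):
        n_per_wave = {year: n_per_wave for year in waves}
    return CohortSpec(waves=waves, n_per_wave=dict(n_per_wave),
                      missingness=missingness or MissingnessSpec())


def _solve_parent_bmi(bands):
    p_normal, p_obese = bands
    z1 = _ppf(p_normal)
    z2 = _ppf(1.0 - p_obese)
    if z2 - z1 < 1e-6:
        return 24.0 - z1, 1.0
    sd = 4.0 / (z2 - z1)
    return 24.0 - z1 * sd, sd


def generate_wave(spec: WaveSpec, n: int, refs: ReferenceSet,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one wave; returns (records, truth)."""
    year = spec.year
    sex = np.where(rng.random(n) < spec.boys_fraction, "male", "female").astype(object)
    is_f = sex == "female"
    age = rng.uniform(spec.age_low, min(spec.age_high, 18.0) - 1e-3, size=n)

    adiposity = rng.standard_normal(n)
    lifestyle = rng.standard_normal(n)

    # height via the height LMS reference
    z_h = rng.standard_normal(n)
    Lh, Mh, Sh = refs.height.params(sex, age)
    height = Mh * (1.0 + Lh * Sh * np.clip(z_h, -4.0, 4.0)) ** (1.0 / Lh)

    # BMI: latent z with exact band targets per sex, through the BMI LMS
    rho_a = spec.adiposity_bmi_loading
    bmi_z_std = rho_a * adiposity + np.sqrt(1 - rho_a**2) * rng.standard_normal(n)
    mu_m, sd_m = _solve_band_normal(spec.bmi_ideal["male"], spec.bmi_poor["male"],
                                    _Z85, _Z95)
    mu_f, sd_f = _solve_band_normal(spec.bmi_ideal["female"], spec.bmi_poor["female"],
                                    _Z85, _Z95)
    bmi_z = np.where(is_f, mu_f + sd_f * bmi_z_std, mu_m + sd_m * bmi_z_std)
    Lb, Mb, Sb = refs.bmi.params(sex, age)
    bmi_z_c = np.clip(bmi_z, -4.5, 5.2)
    bmi = Mb * (1.0 + Lb * Sb * bmi_z_c) ** (1.0 / Lb)
    weight = bmi * (height / 100.0) ** 2

    # body fat percentage and mass
    fmp = (spec.fmp_base + spec.fmp_female_offset * is_f
           + spec.fmp_age_slope * (age - 12.0)
           + spec.fmp_adiposity_slope * bmi_z_std
           + rng.normal(0.0, spec.fmp_noise_sd, size=n))
    fmp = np.clip(fmp, 4.0, 55.0)
    fat_mass = fmp / 100.0 * weight

    # blood pressure through the child's own reference cell
    pct = 100.0 * stats.norm.cdf(refs.height.zscore(sex, age, height))
    bands = assign_height_band(pct, refs.bp.band_edges)
    key = pd.DataFrame({"sex": sex, "age_years": np.floor(age).astype(int),
                        "height_band": bands})
    cells = key.merge(refs.bp.table, on=["sex", "age_years", "height_band"],
                      how="left", validate="many_to_one")
    sbp90 = cells["sbp_p90"].to_numpy(float)
    sbp95 = cells["sbp_p95"].to_numpy(float)
    dbp90 = cells["dbp_p90"].to_numpy(float)
    dbp95 = cells["dbp_p95"].to_numpy(float)
    s_sbp = (sbp95 - sbp90) / (_Z95BP - _Z90BP)
    m_sbp = sbp90 - _Z90BP * s_sbp
    s_dbp = (dbp95 - dbp90) / (_Z95BP - _Z90BP)
    m_dbp = dbp90 - _Z90BP * s_dbp
    rho_bp = spec.bp_adiposity_loading
    z_core = rho_bp * adiposity + np.sqrt(1 - rho_bp**2) * rng.standard_normal(n)
    share = spec.bp_pressure_share
    z_sbp = share * z_core + np.sqrt(1 - share**2) * rng.standard_normal(n) + spec.bp_shift
    z_dbp = share * z_core + np.sqrt(1 - share**2) * rng.standard_normal(n) + spec.bp_shift
    sbp = np.round(m_sbp + s_sbp * z_sbp, 1)
    dbp = np.round(np.minimum(m_dbp + s_dbp * z_dbp, (m_sbp + s_sbp * z_sbp) - 5.0), 1)

    # lipids / glucose: Gaussian copula on the adiposity latent keeps the
    # configured marginals exact while giving overweight children higher
    # TC/FBG on average
    rho_met = spec.metabolic_adiposity_loading
    z_tc = rho_met * adiposity + np.sqrt(1 - rho_met**2) * rng.standard_normal(n)
    z_fbg = rho_met * adiposity + np.sqrt(1 - rho_met**2) * rng.standard_normal(n)
    mu_tc, sig_tc = _lognormal_params(spec.tc_mean, spec.tc_sd)
    tc = np.exp(mu_tc + sig_tc * z_tc)
    fbg = np.maximum(spec.fbg_mean + spec.fbg_sd * z_fbg, 40.0)

    # smoking
    poor_smoke = np.where(is_f, spec.smoking_poor["female"], spec.smoking_poor["male"])
    smoked = (rng.random(n) < poor_smoke).astype(int)

    # physical activity: a single latent percentile drives the whole
    # MVPA distribution, so the poor (0 min) and ideal (>= 60 min)
    # fractions hit their per-sex targets exactly while minutes stay
    # positively correlated with the lifestyle latent
    rho_l = spec.lifestyle_pa_loading
    u_pa = stats.norm.cdf(rho_l * lifestyle + np.sqrt(1 - rho_l**2)
                          * rng.standard_normal(n))
    p_poor_pa = np.where(is_f, spec.pa_poor["female"], spec.pa_poor["male"])
    p_ideal_pa = np.where(is_f, spec.pa_ideal["female"], spec.pa_ideal["male"])
    inter_width = np.maximum(1.0 - p_poor_pa - p_ideal_pa, _EPS)
    frac_inter = np.clip((u_pa - p_poor_pa) / inter_width, 0.0, 1.0)
    frac_ideal = np.clip((u_pa - (1.0 - p_ideal_pa)) / np.maximum(p_ideal_pa, _EPS),
                         0.0, 1.0)
    minutes = np.where(
        u_pa < p_poor_pa, 0.0,
        np.where(u_pa < 1.0 - p_ideal_pa,
                 1.0 + 58.5 * frac_inter,          # (0, 60) intermediate
                 60.0 + 120.0 * frac_ideal))       # [60, 180] ideal

    # diet: five components through the healthy-eater latent
    rho_d = spec.diet_loading
    thr = _ppf(np.asarray(spec.diet_component_probs))
    # satisfied iff the component score falls below its threshold; the
    # negative loading makes a *higher* lifestyle latent produce *better*
    # diet, matching the PA direction (band marginals are unchanged by
    # the sign flip, by symmetry of the latent)
    comp_z = (-rho_d * lifestyle[:, None]
              + np.sqrt(1 - rho_d**2) * rng.standard_normal((n, 5)))
    satisfied = comp_z < thr[None, :]
    u = rng.random((n, 5))
    fv = np.where(satisfied[:, 0], 1.0 + 2.0 * u[:, 0], 0.99 * u[:, 0])
    aq = np.where(satisfied[:, 1], 1.0 + 6.0 * u[:, 1], 0.99 * u[:, 1])
    fried = np.where(satisfied[:, 2], u[:, 2], 1.01 + 5.0 * u[:, 2])
    ssb = np.where(satisfied[:, 3], 0.99 * u[:, 3], 1.0 + 5.0 * u[:, 3])
    bean = np.where(satisfied[:, 4], 1.0 + 2.0 * u[:, 4], 0.99 * u[:, 4])

    # covariates
    income = np.asarray(["poor", "middle", "high"], dtype=object)[
        (rng.random(n)[:, None] > np.cumsum(spec.income_probs)[None, :2]).sum(axis=1)]
    father_edu = (rng.random(n) < spec.father_edu_college).astype(int)
    mother_edu = (rng.random(n) < spec.mother_edu_college).astype(int)
    mu_fb, sd_fb = _solve_parent_bmi(spec.father_bmi_bands)
    mu_mb, sd_mb = _solve_parent_bmi(spec.mother_bmi_bands)
    father_bmi = rng.normal(mu_fb, sd_fb, size=n)
    mother_bmi = rng.normal(mu_mb, sd_mb, size=n)
    cvd = (rng.random(n) < spec.parental_cvd).astype(int)
    parent_smoker = (rng.random(n) < spec.parent_smoker).astype(int)
    u_env = rng.random(n)
    env_days = np.where(u_env < spec.smoke_env_gt1,
                        rng.integers(2, 8, size=n),
                        np.where(u_env < spec.smoke_env_gt1 + 0.10, 1, 0)).astype(float)
    # sedentary >= 2 h correlated with the lifestyle latent (healthier
    # lifestyles sit less)
    u_sed = stats.norm.cdf(0.4 * lifestyle + np.sqrt(1 - 0.16)
                           * rng.standard_normal(n))
    sed_flag = u_sed < spec.sedentary_ge2h
    sed_hours = np.where(sed_flag, 2.0 + rng.exponential(1.2, size=n),
                         2.0 * rng.random(n))
    young = np.floor(age) <= 12
    adequate = rng.random(n) < spec.sleep_adequate_p
    long_side = rng.random(n) < 0.15
    sleep = np.where(
        adequate,
        np.where(young, rng.uniform(9.0, 12.0, n), rng.uniform(8.0, 10.0, n)),
        np.where(long_side,
                 np.where(young, rng.uniform(12.05, 13.5, n),
                          rng.uniform(10.05, 12.0, n)),
                 np.where(young, rng.uniform(6.0, 8.95, n),
                          rng.uniform(5.5, 7.95, n))))
    premature = (rng.random(n) < spec.premature_p).astype(int)
    mature = (rng.random(n) < stats.norm.cdf((age - 12.5) / 1.5)).astype(int)

    records = pd.DataFrame({
        "id": [f"{year}-{i:06d}" for i in range(n)],
        "survey_year": year,
        "sex": sex,
        "age": np.round(age, 2),
        "height_cm": np.round(height, 1),
        "weight_kg": np.round(weight, 2),
        "fat_mass_kg": np.round(fat_mass, 2),
        "sbp": sbp,
        "dbp": dbp,
        "tc_mgdl": np.round(tc, 1),
        "fbg_mgdl": np.round(fbg, 1),
        "smoked_past_30d": smoked,
        "mvpa_min_per_day": np.round(minutes, 1),
        "diet_fruit_veg_per_day": np.round(fv, 2),
        "diet_aquatic_per_week": np.round(aq, 2),
        "diet_fried_fast_per_week": np.round(fried, 2),
        "diet_ssb_per_week": np.round(ssb, 2),
        "diet_bean_dairy_per_day": np.round(bean, 2),
        "sedentary_hours_per_day": np.round(sed_hours, 2),
        "sleep_hours_per_day": np.round(sleep, 2),
        "smoke_env_days_per_week": env_days,
        "parent_current_smoker": parent_smoker,
        "household_income": income,
        "father_edu_college": father_edu,
        "mother_edu_college": mother_edu,
        "father_bmi": np.round(father_bmi, 1),
        "mother_bmi": np.round(mother_bmi, 1),
        "parental_cvd_history": cvd,
        "premature": premature,
        "sexually_mature": mature,
    })
    truth = pd.DataFrame({
        "id": records["id"],
        "survey_year": year,
        "adiposity": adiposity,
        "lifestyle": lifestyle,
        "bmi_z": bmi_z,
        "bmi_z_std": bmi_z_std,
        "z_sbp": z_sbp,
        "z_dbp": z_dbp,
    })
    return records, truth


def generate_cohort(spec: CohortSpec, seed: int,
                    refs: ReferenceSet | None = None,
                    with_missingness: bool = True) -> GeneratedCohort:
    """Generate all waves of ``spec``; reproducible for fixed (spec, seed)."""
    refs = refs or default_reference_set()
    years = sorted(spec.n_per_wave)
    streams = np.random.SeedSequence(seed).spawn(len(years) + 1)
    recs, truths = [], []
    for (year, stream) in zip(years, streams[:-1]):
        rng = np.random.default_rng(stream)
        r, t = generate_wave(spec.waves[year], spec.n_per_wave[year], refs, rng)
        recs.append(r)
        truths.append(t)
    records = pd.concat(recs, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    if with_missingness and spec.missingness.overall_target > 0:
        records = inject_missingness(records, spec.missingness,
                                     np.random.default_rng(streams[-1]))
    return GeneratedCohort(records=records, truth=truth, spec=spec, seed=seed)


def _missing_probs(records: pd.DataFrame, mspec: MissingnessSpec,
                   base_logit: float) -> np.ndarray:
    """Per-record, per-covariate missingness probabilities (n x k)."""
    shift = (records["survey_year"].map(mspec.wave_logit).fillna(0.0).to_numpy(float)
             + records["sex"].map(mspec.sex_logit).fillna(0.0).to_numpy(float))
    logit = base_logit + shift
    p = 1.0 / (1.0 + np.exp(-logit))
    return np.repeat(p[:, None], len(mspec.columns), axis=1)


def inject_missingness(records: pd.DataFrame, mspec: MissingnessSpec,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Blank covariates MAR; metric inputs are never touched.

    The shared base rate is solved (bisection on the logit) so that the
    expected fraction of records with at least one missing covariate
    equals ``mspec.overall_target`` under the realized wave/sex
    composition — the probabilities depend only on observed variables, so
    the mechanism is missing-at-random by construction.
    """
    if mspec.overall_target <= 0:
        return records.copy()

    def any_missing_rate(base_logit):
        p = _missing_probs(records, mspec, base_logit)
        return float(np.mean(1.0 - np.prod(1.0 - p, axis=1)))

    lo, hi = -12.0, 2.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if any_missing_rate(mid) < mspec.overall_target:
            lo = mid
        else:
            hi = mid
    base = (lo + hi) / 2
    p = _missing_probs(records, mspec, base)
    mask = rng.random(p.shape) < p
    out = records.copy()
    for j, col in enumerate(mspec.columns):
        if col not in out.columns:
            continue
        col_mask = mask[:, j]
        if out[col].dtype != object:
            out[col] = out[col].astype(float)
        out.loc[col_mask, col] = np.nan if out[col].dtype != object else None
    return out


def logistic_mar_benchmark(n: int, beta=(-0.5, 0.8, 0.5), miss_rate: float = 0.2,
                           seed: int = 0) -> pd.DataFrame:
    """Small benchmark cohort with a known logistic law and MAR missingness.

    y ~ Bernoulli(expit(b0 + b1 x1 + b2 x2)) with x1 ~ N(0,1) continuous
    and x2 ~ Bernoulli(0.5).  x1 is made missing with probability
    depending on the always-observed (x2, y) — missing at random — at an
    overall rate ``miss_rate``.  Used to check that chained imputation
    plus Rubin pooling recovers b1 with nominal coverage.
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2 = beta
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.5).astype(float)
    p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x1 + b2 * x2)))
    y = (rng.random(n) < p).astype(float)
    # MAR: logit depends on x2 and y; intercept solved for the target rate
    shift = 0.6 * x2 - 0.6 * y
    lo, hi = -8.0, 4.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.mean(1.0 / (1.0 + np.exp(-(mid + shift)))) < miss_rate:
            lo = mid
        else:
            hi = mid
    pm = 1.0 / (1.0 + np.exp(-((lo + hi) / 2 + shift)))
    x1_obs = np.where(rng.random(n) < pm, np.nan, x1)
    return pd.DataFrame({"y": y, "x1": x1_obs, "x2": x2, "x1_true": x1})
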