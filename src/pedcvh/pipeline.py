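"""Pipeline stages, run configuration and publication-shaped outputs.

The pipeline mirrors a survey-analysis workflow: ``simulate`` a
multi-wave cohort (or supply your own participant CSV), ``score`` the
seven CVH metrics against the reference tables, ``report`` wave-level
descriptive tables (score means, per-metric status proportions with
Wilson CIs, score distributions, diet components, trend p-values), and
``associate`` demographic factors with ideal CVH via multiply-imputed
logistic models, plus the attributable fraction of overweight/obesity for
each poor CVH factor.  Every stage writes plain CSVs plus a manifest
entry (seed, config hash, input hashes) so a run is auditable and
byte-reproducible given one master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import run_association_suite
from .cohort import MissingnessSpec, default_cohort_spec, generate_cohort
from .impute import ImputationConfig, impute_chained
from .references import default_reference_set, load_reference_set
from .scoring import (IDEAL, METRICS, POOR, STATUSES, derive_covariates_frame,
                      load_participants, score_cohort)
from .trend import cochran_armitage, prevalence_ci

__all__ = ["RunConfig", "UserError", "run_simulate", "run_score", "run_report",
           "run_associate", "run_all"]


class UserError(ValueError):
    """Configuration or input problem attributable to the caller."""


DEFAULT_PREDICTORS = (
    "sex", "age_group", "household_income", "father_edu_college",
    "mother_edu_college", "father_weight_status", "mother_weight_status",
    "parental_cvd_history", "passive_smoking", "sedentary_flag",
    "sleep_adequate", "premature", "sexually_mature", "fmp_tertile",
    "survey_year",
)

DEFAULT_REFERENCE_LEVELS = {
    "sex": "male", "age_group": "6-11", "household_income": "high",
    "father_weight_status": "normal", "mother_weight_status": "normal",
    "fmp_tertile": "T1", "survey_year": "2004",
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    output_dir: Path = Path("pedcvh_out")
    seed: int = 0
    n_per_wave: int | dict = 2000
    missing_target: float = 0.32
    participants: Path | None = None          # skip simulate when given
    units: dict = field(default_factory=dict)
    reference_paths: dict | None = None       # {bmi, bp, height[, band_edges]}
    ci_method: str = "wilson"
    trend_scores: str = "ordinal"             # or "calendar"
    mi_m: int = 30
    mi_iterations: int = 10
    predictors: tuple = DEFAULT_PREDICTORS
    reference_levels: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS))
    par_bootstrap: int = 200
    par_adjusters: tuple = ("sex", "age_group")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except Exception as exc:
            raise UserError(f"cannot read config {path}: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise UserError(f"unknown config key(s): {sorted(bad)}")
        cfg = cls(**raw)
        cfg.output_dir = Path(cfg.output_dir)
        if cfg.participants is not None:
            cfg.participants = Path(cfg.participants)
        return cfg

    def config_hash(self) -> str:
        payload = {k: str(getattr(self, k)) for k in self.__dataclass_fields__}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def references(self):
        if self.reference_paths is None:
            return default_reference_set()
        rp = dict(self.reference_paths)
        edges = tuple(rp.pop("height_band_edges", (5, 25, 50, 75, 95)))
        try:
            return load_reference_set(rp["bmi"], rp["bp"], rp["height"],
                                      band_edges=edges)
        except KeyError as exc:
            raise UserError(f"reference_paths missing key {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _update_manifest(cfg: RunConfig, stage: str, entries: dict):
    path = cfg.output_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__, "seed": cfg.seed,
        "config_hash": cfg.config_hash(), "stages": {}}
    manifest["stages"][stage] = entries
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return _sha256(path)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig) -> dict:
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    spec = default_cohort_spec(
        n_per_wave=cfg.n_per_wave,
        missingness=MissingnessSpec(overall_target=cfg.missing_target))
    refs = cfg.references()
    gen = generate_cohort(spec, seed=cfg.seed, refs=refs)
    out = {}
    out["cohort"] = _write(gen.records, cfg.output_dir / "cohort.csv")
    out["ground_truth"] = _write(gen.truth, cfg.output_dir / "ground_truth.csv")
    out["n"] = len(gen.records)
    _update_manifest(cfg, "simulate", out)
    return out


def run_score(cfg: RunConfig) -> dict:
    path = cfg.participants or (cfg.output_dir / "cohort.csv")
    if not Path(path).exists():
        raise UserError(f"participant file {path} not found (run simulate first?)")
    records = load_participants(path, units=cfg.units)
    required = {"id", "survey_year", "sex", "age"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise UserError(f"participant file lacks column(s) {sorted(missing_cols)}")
    refs = cfg.references()
    prof = score_cohort(records, refs)
    cov = derive_covariates_frame(records)
    carry = [c for c in ("id", "survey_year", "sex", "age", "household_income",
                         "father_edu_college", "mother_edu_college",
                         "parental_cvd_history", "premature", "sexually_mature")
             if c in records.columns]
    profiles = pd.concat([records[carry], prof, cov], axis=1)
    excluded = profiles.loc[~prof["valid"], ["id", "missing_metrics"]].copy()
    excluded["reason"] = "metric-missing:" + excluded["missing_metrics"]
    out_dir = cfg.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    out = {
        "profiles": _write(profiles, out_dir / "profiles.csv"),
        "exclusions": _write(excluded[["id", "reason"]],
                             out_dir / "exclusions.csv"),
        "n_in": len(records),
        "n_valid": int(prof["valid"].sum()),
        "n_excluded": int((~prof["valid"]).sum()),
    }
    _update_manifest(cfg, "score", out)
    return out


def _trend_scores(cfg, years):
    if cfg.trend_scores == "calendar":
        return [float(y) for y in years]
    return list(range(1, len(years) + 1))


def _ptrend(cfg, frame, indicator):
    """Cochran–Armitage p for a boolean column across survey years."""
    years = sorted(frame["survey_year"].unique())
    if len(years) < 2:
        return np.nan
    ks = [int(frame.loc[frame["survey_year"] == y, indicator].sum()) for y in years]
    ns = [int((frame["survey_year"] == y).sum()) for y in years]
    return cochran_armitage(ks, ns, scores=_trend_scores(cfg, years)).pvalue


def _strata(profiles):
    yield "overall", "all", profiles
    for sex in ("male", "female"):
        yield "sex", sex, profiles[profiles["sex"] == sex]
    for ag in ("6-11", "12-18"):
        yield "age_group", ag, profiles[profiles["age_group"] == ag]


def score_summary_table(cfg: RunConfig, profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of CVH/behavior/factor scores and ideal prevalences with
    CIs, per wave within overall/sex/age-group panels, plus p-trend."""
    valid = profiles[profiles["valid"].astype(bool)].copy()
    valid["ideal_cvh"] = valid["cvh_category"] == IDEAL
    rows = []
    for stratum, level, sub in _strata(valid):
        p_tr = {col: _ptrend(cfg, sub, col) for col in
                ("ideal_cvh", "ideal_behaviors", "ideal_factors")}
        for year in sorted(sub["survey_year"].unique()):
            g = sub[sub["survey_year"] == year]
            row = {"stratum": stratum, "level": level, "survey_year": year,
                   "n": len(g)}
            for score in ("cvh_score", "behavior_score", "factor_score"):
                row[f"{score}_mean"] = g[score].mean()
                row[f"{score}_sd"] = g[score].std(ddof=1)
            for flag in ("ideal_cvh", "ideal_behaviors", "ideal_factors"):
                est = prevalence_ci(int(g[flag].sum()), len(g),
                                    method=cfg.ci_method)
                row[f"{flag}_pct"] = 100 * est.proportion
                row[f"{flag}_ci_low"] = 100 * est.ci_low
                row[f"{flag}_ci_high"] = 100 * est.ci_high
                row[f"{flag}_p_trend"] = p_tr[flag]
            rows.append(row)
    return pd.DataFrame(rows)


def metric_proportions_table(cfg: RunConfig, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-metric poor/intermediate/ideal proportions (95% CI) per wave
    and stratum, with the trend p-value for the ideal level."""
    valid = profiles[profiles["valid"].astype(bool)]
    rows = []
    for stratum, level, sub in _strata(valid):
        for metric in METRICS:
            col = f"status_{metric}"
            sub_m = sub.assign(_ideal=sub[col] == IDEAL)
            p_tr = _ptrend(cfg, sub_m, "_ideal")
            for year in sorted(sub["survey_year"].unique()):
                g = sub[sub["survey_year"] == year]
                n = len(g)
                for status in STATUSES:
                    if metric == "smoking" and status == "intermediate":
                        continue
                    k = int((g[col] == status).sum())
                    est = prevalence_ci(k, n, method=cfg.ci_method)
                    rows.append({
                        "stratum": stratum, "level": level, "metric": metric,
                        "survey_year": year, "status": status, "n": n, "k": k,
                        "pct": 100 * est.proportion,
                        "ci_low": 100 * est.ci_low,
                        "ci_high": 100 * est.ci_high,
                        "p_trend_ideal": p_tr,
                    })
    return pd.DataFrame(rows)


def score_distribution_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Distribution of the 0–7 CVH score and 0–5 diet components by wave."""
    valid = profiles[profiles["valid"].astype(bool)]
    rows = []
    for year in sorted(valid["survey_year"].unique()):
        g = valid[valid["survey_year"] == year]
        for s in range(8):
            rows.append({"survey_year": year, "quantity": "cvh_score",
                         "value": s, "count": int((g["cvh_score"] == s).sum()),
                         "pct": 100 * (g["cvh_score"] == s).mean()})
        for c in range(6):
            rows.append({"survey_year": year, "quantity": "diet_components",
                         "value": c,
                         "count": int((g["diet_components"] == c).sum()),
                         "pct": 100 * (g["diet_components"] == c).mean()})
    return pd.DataFrame(rows)


DIET_COMPONENT_RULES = (
    ("fruit_veg", "diet_fruit_veg_per_day", lambda s: s >= 1),
    ("aquatic", "diet_aquatic_per_week", lambda s: s >= 1),
    ("fried_fast", "diet_fried_fast_per_week", lambda s: s <= 1),
    ("ssb", "diet_ssb_per_week", lambda s: s < 1),
    ("bean_dairy", "diet_bean_dairy_per_day", lambda s: s >= 1),
)


def diet_component_table(records: pd.DataFrame) -> pd.DataFrame:
    """Prevalence of each ideal diet component by wave and sex."""
    rows = []
    for year in sorted(records["survey_year"].unique()):
        g = records[records["survey_year"] == year]
        for sex in ("all", "male", "female"):
            sub = g if sex == "all" else g[g["sex"] == sex]
            for name, col, rule in DIET_COMPONENT_RULES:
                vals = pd.to_numeric(sub[col], errors="coerce").dropna()
                rows.append({"survey_year": year, "sex": sex,
                             "component": name, "n": len(vals),
                             "pct": 100 * rule(vals).mean() if len(vals) else np.nan})
    return pd.DataFrame(rows)


def run_report(cfg: RunConfig) -> dict:
    pro_path = cfg.output_dir / "profiles.csv"
    coh_path = cfg.participants or (cfg.output_dir / "cohort.csv")
    if not pro_path.exists():
        raise UserError("profiles.csv not found; run the score stage first")
    profiles = pd.read_csv(pro_path)
    records = pd.read_csv(coh_path)
    out = {
        "score_summary": _write(score_summary_table(cfg, profiles),
                                cfg.output_dir / "score_summary.csv"),
        "metric_proportions": _write(metric_proportions_table(cfg, profiles),
                                     cfg.output_dir / "metric_proportions.csv"),
        "score_distribution": _write(score_distribution_table(profiles),
                                     cfg.output_dir / "score_distribution.csv"),
        "diet_components": _write(diet_component_table(records),
                                  cfg.output_dir / "diet_components.csv"),
    }
    _update_manifest(cfg, "report", out)
    return out


# ---------------------------------------------------------------------------
# association stage
# ---------------------------------------------------------------------------

ANALYSIS_COVARIATES = (
    "household_income", "father_edu_college", "mother_edu_college",
    "father_weight_status", "mother_weight_status", "parental_cvd_history",
    "passive_smoking", "sedentary_flag", "sleep_adequate", "premature",
    "sexually_mature", "fmp_tertile",
)


def build_analysis_frame(profiles: pd.DataFrame) -> pd.DataFrame:
    """Analysis dataset for the association stage.

    One row per valid profile: the ideal-CVH outcome, complete design
    variables (sex, age group, wave) and the covariates that may carry
    missingness.  Booleans are coerced to 0/1 floats so the imputer can
    model them; the wave is kept as a string so it is reference-coded."""
    valid = profiles[profiles["valid"].astype(bool)].copy()
    frame = pd.DataFrame(index=valid.index)
    frame["ideal_cvh"] = (valid["cvh_category"] == IDEAL).astype(float)
    frame["poor_bp"] = (valid["status_blood_pressure"] == POOR).astype(float)
    frame["poor_tc"] = (valid["status_total_cholesterol"] == POOR).astype(float)
    frame["poor_fbg"] = (valid["status_fasting_glucose"] == POOR).astype(float)
    frame["ow_ob"] = (valid["status_bmi"] != IDEAL).astype(float)
    frame["sex"] = valid["sex"].astype(object)
    frame["age_group"] = valid["age_group"].astype(object)
    frame["survey_year"] = valid["survey_year"].astype(int).astype(str)
    categorical = ("household_income", "father_weight_status",
                   "mother_weight_status", "fmp_tertile")
    for col in ANALYSIS_COVARIATES:
        s = valid[col]
        if col in categorical:
            frame[col] = s.astype(object).where(s.notna(), None)
        else:
            if s.dtype == object:
                lut = {True: 1, False: 0, "True": 1, "False": 0}
                s = s.map(lambda v: lut.get(v, v))
            frame[col] = pd.to_numeric(s, errors="coerce")
    return frame.reset_index(drop=True)


def _par_tables(frame: pd.DataFrame, cfg: RunConfig, seed: int) -> pd.DataFrame:
    """Attributable fraction of overweight/obesity for each poor CVH
    factor, per wave, by model standardization with bootstrap CIs."""
    from .association import build_design, par_model_standardization

    rows = []
    for year in sorted(frame["survey_year"].unique()):
        sub = frame[frame["survey_year"] == year]
        for factor, col in (("blood_pressure", "poor_bp"),
                            ("total_cholesterol", "poor_tc"),
                            ("fasting_glucose", "poor_fbg")):
            y = sub[col].to_numpy(float)
            if y.sum() < 10 or sub["ow_ob"].nunique() < 2:
                continue
            X = build_design(sub, ["ow_ob", *cfg.par_adjusters],
                             reference=cfg.reference_levels)
            res = par_model_standardization(
                y, X.reset_index(drop=True), "ow_ob",
                n_bootstrap=cfg.par_bootstrap, seed=seed)
            rows.append({"survey_year": year, "cvh_factor": factor,
                         "par_pct": 100 * res.estimate,
                         "ci_low": 100 * res.ci_low,
                         "ci_high": 100 * res.ci_high,
                         "n": len(sub), "cases": int(y.sum())})
    return pd.DataFrame(rows)


def run_associate(cfg: RunConfig) -> dict:
    pro_path = cfg.output_dir / "profiles.csv"
    if not pro_path.exists():
        raise UserError("profiles.csv not found; run the score stage first")
    profiles = pd.read_csv(pro_path)
    frame = build_analysis_frame(profiles)
    outcome = "ideal_cvh"
    predictors = [p for p in cfg.predictors if p in frame.columns]

    has_missing = frame[list(ANALYSIS_COVARIATES)].isna().any().any()
    mi_cfg = ImputationConfig(m=cfg.mi_m, iterations=cfg.mi_iterations,
                              seed=cfg.seed + 1)
    if has_missing:
        imputed = impute_chained(frame, mi_cfg, columns=list(ANALYSIS_COVARIATES))
    else:
        imputed = [frame.copy() for _ in range(mi_cfg.m)]
    pooled = run_association_suite(imputed, outcome, predictors,
                                   reference=cfg.reference_levels)
    or_mi = pooled["or_table"].rename_axis("term").reset_index()

    complete = frame.dropna(subset=list(ANALYSIS_COVARIATES))
    cc = run_association_suite([complete], outcome, predictors,
                               reference=cfg.reference_levels)
    or_cc = cc["or_table"].rename_axis("term").reset_index()

    # per-sex stratified MI analysis (same row structure)
    strat_frames = []
    for sex in ("male", "female"):
        sub_imp = [d[d["sex"] == sex].reset_index(drop=True) for d in imputed]
        preds = [p for p in predictors if p != "sex"]
        res = run_association_suite(sub_imp, outcome, preds,
                                    reference=cfg.reference_levels)
        t = res["or_table"].rename_axis("term").reset_index()
        t.insert(0, "stratum", sex)
        strat_frames.append(t)
    or_sex = pd.concat(strat_frames, ignore_index=True)

    # PAR uses only fully observed variables (metric statuses + sex/age)
    par = _par_tables(frame, cfg, seed=cfg.seed + 2)

    out = {
        "or_mi": _write(or_mi, cfg.output_dir / "or_pooled_mi.csv"),
        "or_complete_case": _write(or_cc, cfg.output_dir / "or_complete_case.csv"),
        "or_by_sex": _write(or_sex, cfg.output_dir / "or_by_sex.csv"),
        "par": _write(par, cfg.output_dir / "par_overweight_obesity.csv"),
        "m": mi_cfg.m,
        "n_analysis": len(frame),
        "n_complete": len(complete),
    }
    _update_manifest(cfg, "associate", out)
    return out


def run_all(cfg: RunConfig) -> dict:
    out = {}
    if cfg.participants is None:
        out["simulate"] = run_simulate(cfg)
    out["score"] = run_score(cfg)
    out["report"] = run_report(cfg)
    out["associate"] = run_associate(cfg)
    return out
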