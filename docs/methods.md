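# Methods

`pedcvh` implements the modified-AHA cardiovascular-health (CVH) construct
for children and adolescents and the survey-analysis machinery around it.
This note documents the models, the grading conventions, the synthetic
cohort the pipeline is exercised on, and the numerical choices that were
genuinely open.

## The CVH construct

Seven metrics are graded `poor` / `intermediate` / `ideal`: four health
behaviors — smoking, BMI, physical activity, diet — and three health
factors — blood pressure, total cholesterol, fasting glucose.  The CVH
score counts ideal metrics (0–7); categories are poor (0–2), intermediate
(3–5) and ideal (6–7).  The behavior score (0–4) is "ideal behaviors" at
3–4; the factor score (0–3) is "ideal factors" only at 3.

Grading thresholds and the boundary conventions used to make every real
input classifiable:

| metric | poor | intermediate | ideal |
|---|---|---|---|
| smoking | smoked in prior 30 d | — | did not |
| BMI | > 95th pct | [85th, 95th] pct | < 85th pct |
| physical activity | 0 min/d | (0, 60) min/d | ≥ 60 min/d MVPA |
| diet | 0–1 components | 2–3 | 4–5 of 5 |
| blood pressure | > 95th pct | ≥ 90th pct, or SBP ≥ 120 / DBP ≥ 80 mmHg | otherwise |
| total cholesterol | ≥ 200 mg/dL | [170, 200) | < 170 |
| fasting glucose | ≥ 126 mg/dL | [100, 126) | < 100 |

Conventions worth stating explicitly: the lab bands are half-open real
intervals so non-integer values are gapless; percentile boundaries follow
the strict printed inequalities (a BMI exactly at the 85th or 95th
percentile is intermediate; poor requires strictly above the 95th); for
blood pressure the worse of SBP/DBP governs and the absolute 120/80 rule
can only worsen an ideal classification to intermediate; exactly 0
minutes of MVPA is poor, any positive amount below 60 is intermediate.
The five diet components are fruits/vegetables ≥ 1/day, aquatic foods
≥ 1/week, fried or fast food ≤ 1/week (inclusive), sugar-sweetened
beverages < 1/week (strict), and bean-curd/dairy ≥ 1/day.

Records missing any of the seven metric inputs are excluded from CVH
scoring (flagged, never silently dropped); covariate missingness is
retained and handled by multiple imputation.

Units are canonical mg/dL internally; the loader converts declared
mmol/L columns (total cholesterol × 38.67, glucose × 18.016).

## Reference standards

BMI and height references use the LMS representation (Box–Cox power L,
median M, coefficient of variation S per sex and age):
z = ((x/M)^L − 1)/(L·S), with the log branch at L = 0.  L, M, S are
interpolated linearly in age between grid points; ages outside the grid
are a hard error — silent extrapolation would corrupt classification.
Blood-pressure references are a complete grid over sex × completed age ×
height-percentile band.  The height band is derived from the height LMS
reference; bands are half-open intervals closed on the left, with a
percentile exactly at an edge assigned to the upper band.  Band edges
default to (5, 25, 50, 75, 95) and are configurable; a banded lookup was
chosen over continuous height percentiles as the form in which such
standards are published.

The national reference publications are not redistributable data files,
so the package ships *synthetic* tables (`pedcvh.tables`): smooth LMS
curves with realistic magnitudes and a complete BP grid rising linearly
in age and height band.  They make the pipeline runnable and testable;
they are not the published standards, and user tables in the documented
TSV layout can be substituted.

## Synthetic cohort generator

The generator emulates three cross-sectional waves (2004, 2014, 2019) of
children aged 6–18.  Its defaults are the study conditions the analysis
assumes; they are not fitted to any individual-level data.

Structure per wave:

* **Latents.** A standard-normal *adiposity* factor drives BMI
  (loading 0.70), blood pressure (0.45), fat-mass percentage, and — via a
  Gaussian copula that leaves the configured marginals exact — total
  cholesterol and glucose (0.25).  A *lifestyle* factor drives physical
  activity, the five diet components (loading 0.50 each) and sedentary
  time.  True inter-metric correlations are unreported for such surveys;
  these loadings are stated assumptions chosen to give the associations
  the analysis needs a realistic, testable structure.
* **Exact marginal control.** Metric inputs are drawn through the same
  reference tables the scorer classifies against, so band probabilities
  are controlled in closed form: the BMI latent normal is solved from the
  per-sex (ideal, poor) targets; MVPA minutes are a monotone transform of
  a single latent percentile, making the poor (0 min) and ideal (≥60 min)
  fractions exact; TC is log-normal and FBG normal with wave-specific
  moments, so their band probabilities are analytic; diet band
  probabilities follow from the latent-factor model by Gauss–Hermite
  quadrature (`diet_band_probs`).
* **Blood pressure.** Each child's SBP/DBP are placed relative to their
  own reference cell (the within-cell scale is inferred from the p90/p95
  spread), so percentile bands are controlled; because the absolute
  120/80 mmHg rule also binds in older/taller cells, the wave-level
  location shift was calibrated once by large-sample Monte Carlo through
  the actual generate→score path and frozen in the presets together with
  the resulting ideal-BP target.
* **Wave presets.** Per-sex marginal targets follow the published
  direction and approximate level of a Beijing school-survey series
  (ideal BMI monotone decreasing across waves; ideal activity and diet
  lowest in the middle wave; the U-shaped ideal-CVH trend).  The presets
  are qualitative calibrations: no preset output reproduces an actual
  survey estimate, and the implied targets are exposed as
  `WaveSpec.implied_ideal_targets()` so recovery tests compare the
  pipeline against the generator's own configuration, never against
  published numbers.
* **Covariates.** Household income, parental education/BMI/CVD history,
  passive smoking (smoking environment > 1 day/week or a parent who
  smokes), sedentary time (≥ 2 h/day), sleep adequacy (9–12 h at ages
  6–12, 8–10 h at 13–18, with age 12 in the younger band), prematurity
  and sexual maturity are drawn from wave-specific marginals.  Parental
  weight status uses normal < 24, overweight 24–<28, obesity ≥ 28 kg/m².
  Fat-mass percentage tertiles are computed within wave because
  body-composition devices differ across waves; pooling would change
  what a tertile means.
* **Missingness.** Only covariates are ever blanked — never the seven
  metric inputs.  Per-covariate blanking probabilities depend on observed
  wave and sex (logit shifts ±0.25 and ±0.15), making the mechanism MAR
  by construction; the shared base rate is solved by bisection so the
  expected fraction of records with ≥ 1 missing covariate equals the
  configured overall target (default 32%).

What the generator does **not** emulate: school-level clustering and
design weights, device/laboratory measurement error, questionnaire recall
bias, non-uniform age pyramids, secular height trends, and
covariate–metric confounding beyond the two latent factors.  Passing
recovery tests therefore demonstrates the correctness of the analysis
machinery under known conditions, not properties of any real population.

## Statistics

* **Prevalence intervals** use the Wilson score interval (the interval
  method is typically unstated in survey reports; Wilson has good
  small-sample behavior).  Clopper–Pearson is available by option.
* **Trend across waves** uses the Cochran–Armitage statistic
  Z = Σ sᵢ(xᵢ − nᵢ·p̄) / √(p̄(1−p̄)(Σ nᵢsᵢ² − (Σ nᵢsᵢ)²/N)) with ordinal
  wave scores 1..k by default; calendar-year scores are an option since
  the choice is rarely reported.  The test suite validates the asymptotic
  p-value against an exhaustive conditional permutation distribution on
  small tables, using the mid-p convention (half weight on the observed
  statistic's probability) which is the appropriate comparison between a
  continuous approximation and a discrete exact distribution.
* **Descriptives** use one-way ANOVA for continuous and Pearson
  chi-squared (no continuity correction by default) for categorical
  variables.
* **Logistic models** are fitted by IRLS to a deviance-change tolerance
  of 1e−8, with Wald CIs on the log-odds scale (the standard reporting
  match for odds ratios).  Perfect separation is detected by coefficient
  divergence and raised as an error rather than penalized; rank-deficient
  designs raise an error naming the collinear columns.  Categorical
  predictors are reference-coded with configurable reference levels.
* **Attributable fraction** of an exposure uses model-based
  standardization: AF = 1 − (mean predicted risk with the exposure at its
  reference level) / (observed case fraction).  In the unadjusted
  binary-exposure case this equals Miettinen's p_c(RR−1)/RR identically;
  Levin's p_e(RR−1)/(1+p_e(RR−1)) and Miettinen's formulas are shipped as
  closed-form validation companions.  CIs come from a seeded
  nonparametric bootstrap (default 500 resamples; percentile method) —
  simpler to verify against resampling truth than the delta method, at
  some computational cost.
* **Multiple imputation** uses chained equations: per-variable
  conditional models (linear with normal draws for continuous — PMM
  optional — logistic draws for binary, multinomial draws for
  categorical), each refitted on a bootstrap resample of the observed
  rows before drawing, so that between-imputation variance is positive;
  plain deterministic regression imputation is rejected because it
  collapses B.  Defaults: m = 30 completed datasets, 10 chained
  iterations; convergence is monitored informally by chain means.
  Downstream estimates are pooled by Rubin's rules — Q̄ = mean,
  T = W̄ + (1+1/m)·B — with Barnard–Rubin degrees of freedom
  (m−1)(1 + W̄/((1+1/m)B))² and t-based intervals.

## Test design notes

Stochastic checks are seeded and sized so their false-alarm probability
is controlled: the generator-recovery check compares 21 wave × metric
marginals against their configured targets with Wilson 95% intervals at
n = 5,000/wave, and — because 21 simultaneous 95% checks on a *correct*
generator are expected to miss occasionally — allows up to 3 interval
misses while requiring every estimate within 2.5 percentage points of
target (the joint false-failure probability of this rule is below 3%).
Coverage checks (logistic Wald CI ≈ 95% over 500 null simulations;
MI pooled CI ≥ 90% over 50 replications at n = 3,000, 20% MAR, m = 5
scaled down from 30) use fixed seeds and bands wide enough for their
Monte-Carlo error.  Problem sizes throughout (n = 5,000/wave for
recovery, 2,000 null tables for the trend test's type-I error,
n = 4,000/wave with m = 10 in the headline recomputation script) were
chosen as the smallest that make the Monte-Carlo error small relative to
the quantities asserted.

## Known limitations

* The shipped reference tables are synthetic; absolute prevalences
  produced with them are not comparable to published national estimates.
* The generator's latent-factor correlation structure is an assumption;
  association magnitudes produced by the pipeline describe the synthetic
  conditions only.
* PAR bootstrap CIs ignore the imputation step's sampling noise when the
  exposure/outcome are fully observed (as here, where both derive from
  complete metric data).
* Separation in logistic fits is an error by design; no Firth or
  penalized fallback is provided.
* No survey weights or clustering adjustments (crude proportions by
  design).
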