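# Methods

This note documents the models, parameter choices and numerical decisions
behind `stepcea`, and states what the synthetic-data tests do and do not show
about real data.

## Analysis model

The evaluation takes the health-care payer perspective over a one-year
horizon (no discounting) and follows intention-to-treat: participants are
analysed by randomized arm regardless of adherence. Costs cover physician,
outpatient and inpatient services in 2017 Canadian dollars; a price-year
scale factor (`AnalysisConfig.price_scale`, default 1.0) rescales costs
supplied in another price year.

### Two-part cost structure

Whether a participant uses services at all is handled by the decision tree;
how much users cost is handled by regression. The tree's five branches are
exactly the observed service-use combinations (none / physician only /
physician + outpatient / physician + inpatient / all three); there are no
outpatient-only or inpatient-only branches because essentially all specialist
contact in this system is physician-mediated. External records that
nevertheless show such patterns are mapped to the nearest branch containing
their sectors and counted in the log.

Expected cost per participant is the branch-probability-weighted sum of
branch costs, where a branch cost is the sum of its sectors' mean costs
among users. Mix probabilities come from classified counts (not from rounded
printed percentages) whenever a cohort is available; in table-reproduction
mode the printed counts are used and normalized by their actual sum.

### Cost cleaning and adjustment

* **Trimming.** Physician and outpatient costs are trimmed per
  arm × period × sector among users with the Tukey boxplot rule: values
  outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are excluded. Quartiles use linear
  interpolation between order statistics (numpy's default, R type 7); the
  convention is recorded in every `TrimReport` so results are auditable.
  Trimming removes cost *observations*, not participants, and is not
  idempotent (fences are recomputed on each input). Inpatient costs are never
  trimmed: admissions are rare and expensive, and trimming them would
  systematically delete real spending.
* **Imputation.** Missing 12-week outcomes (PHQ-9, EQ-5D) are multiply
  imputed by chained equations with predictive-mean-matching draws
  (statsmodels MICE) conditioning on arm, age, sex and both baseline scores;
  default m = 20 completed datasets. Downstream estimates are pooled by
  Rubin's rules (pooled estimate = mean of estimates; total variance =
  within + (1 + 1/m)·between). Baseline fields are required complete.
* **Regression adjustment.** Sector costs among users are fitted with a gamma
  GLM and identity link (linear mean in age, sex, baseline PHQ-9 and arm);
  the gamma family suits right-skewed costs while the identity link keeps arm
  contrasts in dollars. Fitting is IRLS (tolerance 1e-8, max 100 iterations)
  with a fallback start at the OLS coefficients; fits with non-positive
  fitted means are rejected. 12-week outcomes use OLS on arm + baseline
  score. All arm estimates are predictions at the pooled covariate means
  (recycled-population standardization) so every arm is evaluated on the same
  covariate profile. Strata with fewer than 10 users per arm fall back to the
  raw user mean and are flagged.

### Effectiveness

QALYs are the exact area under the piecewise-linear utility path over
52 weeks, with linear interpolation between baseline and week 12. The three
persistence scenarios reduce to weighted means `w0·u0 + w12·u12`:
carry-forward (3/26, 23/26), linear return to baseline (1/2, 1/2), immediate
return (23/26, 3/26). When u12 > u0 the scenarios are ordered carry-forward ≥
linear ≥ immediate. Utilities outside [0, 1] are rejected — the instrument's
utility scale is anchored at 0 (death) and 1 (full health).

### Probabilistic sensitivity analysis

Each arm's total cost is sampled from a gamma distribution
(shape = mean²/sd², scale = sd²/mean) and its QALY from a normal truncated to
[0, 1], 10,000 iterations by default; both families are overridable and all
sampling flows through latent standard normals so a copula correlation knob
(default 0, arms independent) is available. The spreads used are the
uncertainty of the arm *means* (delta-method: multinomial mix covariance plus
sector-mean standard errors; in table-reproduction mode the printed s.d.
values) — this interpretation reproduces the reported ~55% below-threshold
scatter fraction, whereas reading the printed s.d. as patient-level spreads
would not. The reported 95% CIs on cost/QALY differences are much narrower
than these spreads imply; the source does not reconcile the two, and the
scatter-consistent reading is implemented.

CEACs are 4-way by default: at each willingness-to-pay λ on the 0:200,000:1,000
grid, the probability an arm is cost-effective is the fraction of iterations
in which it attains the maximum net monetary benefit among all arms, with
ties split equally (measure-zero for continuous families, well defined for
degenerate fixtures). Probabilities therefore sum to exactly 1 at every λ.
Pairwise curves and the scatter below-line fraction (Δcost < λ·ΔQALY) are
definitionally identical on the same draws and are computed from the same
draws. Dominated-arm exclusion from scatterplots is a reporting choice, not
an estimation step. ICERs from point estimates are classified dominant
(cheaper, more effective), dominated (costlier, less effective), or
trade-off with ratio Δcost/ΔQALY; ΔQALY = 0 is flagged degenerate with no
ratio.

## Synthetic cohort generator

The generator emulates the trial's published structure so the pipeline is
testable without the undeposited administrative data. Defaults are the
published values: per-arm sizes 412 / 397 / 415 / 183, per-arm score moments
(overall and depressed subgroup), per-arm service mixes, and one-year sector
user costs.

* **PHQ-9 as a two-component mixture.** A single truncated normal cannot
  match the overall mean/sd (≈4.6/5.0) *and* the ≈15% share above 10
  simultaneously. Scores are therefore drawn as a mixture: a depressed
  component on 11–27 at the published subgroup moments and a non-depressed
  component on 0–10 whose moments are derived by complement, so the overall
  mean, sd and depressed fraction all hold by construction. Each component is
  a rounded, clipped normal whose latent parameters are solved numerically
  (exact discrete pmf moments, hybrid root-finder) so the *post*-clipping
  moments hit the targets — clipping at instrument bounds otherwise biases
  both moments.
* **EQ-5D** utilities are clipped normals on [0, 1] calibrated the same way
  (the solve naturally produces a ceiling mass at 1.0, as real EQ-5D data
  show), coupled to PHQ-9 within components by a Gaussian copula with latent
  correlation −0.5. The mixture adds between-component correlation, so the
  marginal PHQ-9↔EQ-5D correlation is stronger (≈ −0.7) than the
  within-component value — consistent with the instruments measuring the same
  underlying severity. 12-week scores carry a longitudinal latent correlation
  of 0.5 with baseline (configurable); both coupling values are generator
  choices, as the source reports marginals only.
* **Costs.** Among users, each period × sector cost is gamma with
  shape = mean²/sd², scale = sd²/mean; sectors absent from the drawn
  combination are exact zeros in every period. One-year user means/sds are
  split between the 12-week post period and the 12-week-to-1-year period in
  proportion to length (12/52, 40/52); the pre-randomization period uses the
  published by-status pre-period costs pooled over depression status (the
  source does not print pre-period costs by arm). Costs are independent of
  depression status and of covariates by default; a `cost_outcome_corr` knob
  couples costs to baseline PHQ-9 through a copula when a correlation is
  wanted, since no within-arm cost-outcome correlation is reported.
* **Contamination.** High-cost outliers multiply a 5% fraction of physician
  and outpatient cost cells by 10 (inpatient untouched, since it is never
  trimmed); missing 12-week outcomes default to 15% per arm under a
  missing-at-random mechanism whose dropout probability increases with
  baseline PHQ-9 (logistic, slope 1 per baseline sd, intercept solved so the
  expected rate is exact). The source quantifies neither rate; both are
  generator choices representing visible-but-moderate contamination, and both
  are configurable down to zero.
* **Determinism.** One integer seed drives everything (generation, outliers,
  missingness derive child seeds from it); identical configurations produce
  byte-identical CSV serializations.

**What passing tests show — and don't.** The generator matches published
*summary* structure: marginal moments, mixture shares, service-mix
frequencies, skewed cost shapes, contamination. It does not reproduce
clinic-level clustering, billing-event timing, drug-level costs, within-arm
cost-outcome dependence (off by default), or any feature of the real joint
distribution beyond the published margins. Pipeline correctness on synthetic
data therefore demonstrates estimator consistency under the stated model, not
agreement with the undeposited patient-level data.

## Numerical and design choices

* Quantile convention for trimming: type 7 (linear interpolation), recorded
  per trim report.
* Depressed subgroup is strictly PHQ-9 > 10 at baseline, matching the
  description of the subgroup size; the common screening convention elsewhere
  is ≥ 10.
* The published service-count table is internally inconsistent (three arm
  rows' counts sum to 415/399/422 against printed totals 412/397/415).
  Probabilities are normalized by the actual count sum, the only reading that
  yields a valid probability vector; the discrepancies are < 0.004 per
  branch.
* Gamma GLMs are fitted per period separately ("year" = post + late user
  totals feeds the tree); whether the original analysis pooled periods is
  unstated.
* Whether the reported QALYs used adjusted or raw utilities is unstated;
  adjusted 12-week utilities are used and the agreement tolerance (±0.01)
  absorbs the difference.
* 1 year = 52 weeks exactly; the 12-week mark sits at 12/52.
* Baseline-to-12-week utility is linearly interpolated; a step function would
  move QALYs only in the fourth decimal and is not exposed.
* Degenerate inputs: sd = 0 anywhere produces deterministic draws; empty
  trim vectors, rates ≥ 1, multipliers ≤ 1, probabilities off the simplex,
  utilities outside [0, 1] and 100%-missing columns raise typed errors naming
  the offending quantity.

## Problem sizes used in the tests

Moment-recovery checks run at n = 10,000 (single pooled-calibration arm) and
n = 100,000 (service mix); regression-recovery checks at n = 20,000; the
full-pipeline parameter-recovery check generates 50,000 participants per arm
and compares pipeline output to the analytic tree/AUC values within 3 Monte
Carlo standard errors. That check runs on the clean configuration — no
missingness, no contamination, trimming off, single-component scores, common
EQ-5D baseline across arms — because only there are the analytic values exact
expectations of the estimators: trimming an uncontaminated gamma sample
removes real tail mass (a ~0.5–1% downward bias on user means, visible at
these n), and unequal baselines shift standardized predictions away from the
raw configured means. Trimming behaviour under contamination is covered
separately: injecting 5% × 10 outliers moves trimmed means by < 1% while raw
means jump by > 20%.

## Known limitations

* Costs are depression-independent within arm by default, so synthetic
  depressed-subgroup cost contrasts are attenuated relative to the published
  ones (the depressed-subgroup *analysis path* is still fully exercised, and
  table-reproduction mode uses the printed subgroup inputs directly).
* The PSA samples arms independently; any true between-arm correlation
  (e.g. shared unit costs) would narrow incremental uncertainty.
* Implementation/set-up costs of the stepped-care programme, societal costs
  (productivity, transportation) and value-of-information analysis are out of
  scope, as is any Markov/state-transition extension of the one-year tree.
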