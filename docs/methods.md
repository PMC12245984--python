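# Methods

This note records what the package computes, the statistical choices
behind each component, the default parameters and why they were chosen,
and the known limitations.

## 1. Synthetic cohort generator (`t1dpred.cohort`)

Real natural-history cohorts of autoantibody-positive relatives are not
public, so the package generates one with a fully known ground truth.

**Structure.** Each participant gets demographics (sex, age), a genetic
risk score (GRS2), an autoantibody profile drawn from a configurable
stage mix, OGTT glucose and C-peptide curves, HbA1c, and an enrolment
date uniform over an accrual window. A latent progression factor couples
the metabolic variables so that high-risk participants jointly show
higher glucose AUC, lower C-peptide AUC and more autoantibodies.

**Event times.** Progression times follow a Weibull
proportional-hazards model: `S(t | x) = exp(−(t/λ)^k · exp(β·(x − c)))`
with shape `k = 1.10`, scale `λ = 17.5` years, and log-hazard weights
`β` on GRS2 (0.18), autoantibody count (0.55), glucose AUC (0.35),
C-peptide AUC (−0.25) and HbA1c (0.04), each centred at a typical value
`c`. Observed follow-up is the minimum of the event time, an exponential
dropout time (rate 0.065/year) and the administrative horizon (end of
accrual plus a 3-year extension, measured from each enrolment date).

**Calibration.** Defaults were chosen to match published cohort
marginals: n = 3967 eligible, 49% female, age 14.9 ± 12.1 (truncated
normal on [1, 50], parameters solved by least squares so the *truncated*
moments match), median follow-up ≈ 4.7 years, ≈ 33% progressing, stage
mix 45/35/20. The dropout rate and Weibull scale were set once by
matching the median follow-up and progression fraction and then frozen.

**Why Weibull PH?** It gives closed-form survival for oracle tests
(`weibull_survival`), makes Cox-model coefficient recovery a sharp
statistical test (the generator's weights are the estimand), and is the
standard simulation design for survival methodology.

**Realism limits.** Covariates are conditionally Gaussian; OGTT curves
are smooth templates plus noise, without the bimodality and floor
effects of real metabolic data; dropout is independent of covariates
(so IPCW with a marginal censoring KM is exactly correct — real data
may need covariate-dependent censoring models); calendar-time trends in
enrolment characteristics are absent, which makes the temporal split
less adversarial than in a real registry.

## 2. Features and staging (`t1dpred.features`)

- **Eligibility.** Participants at diabetes-level glycaemia (fasting
  glucose ≥ 7.0 mmol/l, 2-h ≥ 11.1 mmol/l, or HbA1c ≥ 48 mmol/mol,
  thresholds inclusive) or with incomplete records are excluded; every
  exclusion is logged with a reason.
- **Staging.** Single autoantibody → `single_ab`; multiple
  autoantibodies with all glycaemia below the impaired band (fasting
  < 5.6, 2-h < 7.8 mmol/l, HbA1c < 39 mmol/mol) → `stage1`; multiple
  with any impaired value → `stage2`.
- **OGTT AUCs** use the trapezoidal rule over the 0/30/60/90/120-minute
  grid, divided by 120 so the result is a time-averaged concentration.
- **Index60** uses the published formula
  `0.3695·ln(C-pep0) + 0.0165·glucose60[mg/dl] − 0.3644·C-pep60`
  (mmol/l → mg/dl factor 18.016). Other composite scores in the
  registry (`score_registry_synthetic.yaml`) carry synthetic placeholder
  coefficients, clearly marked as such: the registry mechanism, not the
  placeholder values, is the deliverable.
- **BMI z-scores** use the LMS method against a packaged synthetic
  growth-reference table (ages 1–20; adults use the age-20 row).
  Substitute a real reference table for real analyses.

## 3. Model space (`t1dpred.model_space`)

All non-empty subsets of the variable catalogue, filtered by
mutual-exclusion groups for near-collinear pairs (bmi ⊥ bmi_z, age ⊥
log_age, ia2a_flag ⊥ ab_combination), ordered by size then
lexicographically so any truncation is deterministic and varied. The
default 15-variable catalogue yields 13823 admissible models; the test
suite verifies the enumeration against brute-force subset filtering.

## 4. Fitting (`t1dpred.fitting`)

- **Temporal split** at an enrolment cutoff (default 2013-01-31):
  earlier enrolments train, later ones validate. All reported metrics
  are validation-only.
- **Cox PH** via lifelines (Efron ties). The Breslow baseline cumulative
  hazard is stored at the training covariate means; absolute risk is
  `1 − exp(−H0(t)·exp(β·(x − x̄)))` with a right-continuous step
  interpolation of `H0`. Horizons beyond the last training event raise
  `ExtrapolationError` rather than silently extrapolating.
- **Random survival forest** via scikit-survival (log-rank splitting;
  defaults 200 trees, minimum leaf 15, √p features). A test verifies a
  depth-1 single tree reproduces the exhaustive best log-rank split.
- **Failure isolation.** Degenerate inputs (no events, constant
  covariates, non-convergence) return a `FitFailure` record; the
  pipeline logs it and continues, so one pathological stage × model cell
  never aborts a run.

## 5. Metrics (`t1dpred.metrics`)

- **IPCW weights.** Cases (event ≤ t) weigh `1/G(T−)` with `G` the
  Kaplan–Meier censoring-survival estimate and `G(T−)` its left limit;
  controls (at risk beyond t) weigh `1/G(t)`; early censored subjects
  weigh 0. Weights are untruncated by default (a warning fires above
  50; `max_weight` clips on request).
- **Time-dependent AUC** is the weighted probability that a case
  outranks a control (cumulative/dynamic definition), computed in
  O(n log n) by sorting, with ties counted one half. Verified exactly
  against brute-force Mann–Whitney when uncensored and to machine
  precision against `sksurv.metrics.cumulative_dynamic_auc` when
  censored.
- **Brier score** is the weighted mean squared error between predicted
  horizon risk and observed status (Graf estimator), matching
  `sksurv.metrics.brier_score` to machine precision.
- **AUC comparison** uses the iid influence-function representation of
  the IPCW AUC, treating the censoring weights as known — a first-order
  simplification of the fully augmented estimator. It reduces exactly
  to the DeLong-type two-sample variance without censoring; with
  censoring it is mildly conservative/liberal depending on the
  censoring pattern, and the test suite brackets it against a paired
  bootstrap. Confidence intervals are logit-transformed.
- **Similar-performance rule.** A model is indistinguishable from the
  best when |ΔAUC| < 0.03 *and* the pairwise p-value > 0.05; both
  conditions are required, and the best model is not in its own set.
- **Variable importance** is permutation-based on the validation split:
  mean AUC drop over seeded permutations.

## 6. Economics (`t1dpred.economics`)

- **Participant time:** OGTT sampling duration + 45 min overhead
  (165/135/105/75 min for 120/90/60/30-min OGTTs); blood draw 10 min.
  For a model, participant time is the **maximum** over its procedure
  groups — one visit, the longest procedure bounds the stay.
- **Clinician time** is shared (max) among variables in the same
  procedure group and summed across groups; a `sum` policy is available
  for sensitivity analysis.
- **Rate card:** physician $2.48/min, assistant $0.46/min, participant
  wage $0.26/min (2024 USD). These were solved from a published
  per-variable cost table so that every per-variable total is
  reproduced to the printed cent; the cost table itself
  (`data/cost_table.csv`) carries HCPCS-style bundle prices per
  variable.

## 7. Pareto selection (`t1dpred.pareto`)

Objectives per model: financial cost, participant minutes (both
minimised) and per-stage 3-year AUC (maximised) and Brier (minimised) —
eight objectives by default, or four with stage-averaged performance.
Dominance is weak-inequality-everywhere plus strict-somewhere; identical
vectors do not dominate each other, so duplicated trade-offs are both
retained. The front is grouped into interpretable tiers: near-best but
expensive OGTT models, balanced mid-cost models, and cheap/fast
no-OGTT models.

## 8. Pipeline (`t1dpred.pipeline`)

One call runs generate → filter → features → enumerate → per-stage
temporal split → fit → validate → cost → Pareto, persisting every
intermediate (cohort, exclusion log, space, metrics, costs, objective
vectors, front, failure log) plus a manifest with library versions,
seeds, counts and timings. Stages whose primary-horizon metrics are
globally undefined drop out of the objective vector; models with
partially missing metrics are excluded from the Pareto comparison and
logged.

## Numerical choices

- All randomness flows from a single `numpy.random.default_rng(seed)`
  per component; same seed ⇒ byte-identical outputs.
- Step-function interpolation is right-continuous everywhere
  (Kaplan–Meier, Breslow baseline), with `searchsorted` rather than
  dense grids.
- Sorting uses stable mergesort wherever order ties could otherwise
  introduce nondeterminism.
- Currency is reported to one decimal; internal arithmetic is double
  precision throughout.

## Limitations

- The synthetic generator is a methodological testbed, not an
  epidemiological model; absolute AUC/Brier values on it do not
  transfer to any real cohort.
- Placeholder registry coefficients (all scores except Index60) mean
  those models' relative performance on synthetic data is arbitrary.
- The AUC-comparison variance ignores the estimation error of the
  censoring KM; for heavily censored data prefer the bootstrap.
- Costs use a single national rate card; no discounting, site variation
  or repeat-visit schedules are modelled.
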