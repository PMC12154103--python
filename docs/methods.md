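# Methods note

## Setting

We estimate the effect of physical activity (and of limited sitting
time) on three binary mental-health outcomes — depression, suicidal
ideation and heavy stress — among survey respondents aged 60+.
Activity is self-selected, so naive arm comparisons are confounded:
self-rated health in particular predicts both activity and outcomes.
All estimation runs on synthetic cohorts whose generator exposes the
per-unit ground truth, so every quantity the package reports can be
validated against a known answer.

## Synthetic cohort generator (`paxlearn.synthetic`)

Each respondent draws 13 covariates from independent marginals
calibrated to published elderly-survey tables (for example, 55.5%
female, 73.9% positive self-rated health, 51.1% hypertension).
Binary latents are expanded into raw survey labels (5-point Likert
scales, yes/no) so that preprocessing performs real recoding work.

* **Treatment.** `P(t=1|x) = expit(a + x·β)` with default confounding
  coefficients `β = {health_perception: +1.0, age_std: −0.5}`. The
  intercept `a` is calibrated by root-finding (Brent's method) so the
  mean propensity equals the target prevalence (3% for
  high-intensity, 14.73% for moderate activity).
* **Outcomes.** Control-arm probability `p₀(x) = expit(a + x·γ)` with
  the intercept calibrated to the configured base rates (14.02%
  depression, 6.09% ideation, 18.75% stress); self-rated health
  carries the dominant coefficient. The treated-arm probability is
  `p₁ = clip(p₀ − τ(x), 0, 1)`: **positive τ means activity reduces
  the outcome probability**.
* **Sitting hours.** Normal truncated at 0 with μ = 7.43, σ = 4.36,
  least-squares fitted so that the shares below 4/6/8/10/12 hours
  match the published cut-point table.
* **Missingness.** Sentinel answers (`no_response`, `do_not_know`,
  `missing`) are injected independently per eligible field. The study
  configuration uses rate 0.067 over 16 fields, so complete-case
  screening keeps about `(1−0.067)¹⁶ ≈ 31%` of the 21,508-row extract
  — matching the source survey's attrition from raw extract to
  analysis cohort (~7,000 rows).

Benchmark conditions: `recovery_config(tau, …)` sets a 0.5 outcome
base rate and moderate coefficients so a constant τ is realised
without clipping (the generator truth then equals τ exactly);
`study_config(seed)` is the full emulation above. The generator
defaults *are* the study conditions; they were fixed before any
estimator results were inspected and are never tuned to them.

**Scope and limits of the emulation.** Covariates are drawn
independently, so real-world covariate correlations (e.g. education ×
income) are absent; confounding strength is set by two coefficients
rather than estimated from data; survey weights, clustering and
multi-year pooling are not modelled.

## Preprocessing (`paxlearn.preprocessing`)

Screening keeps respondents aged ≥ 60 (age first), then drops any row
with a sentinel in one of the 19 analysis columns; the audit counts
`rows_read = rows_kept + dropped_age + dropped_sentinel`. Recodes:
self-rated health is positive for the top three Likert levels; heavy
stress for the top two of five; depression/ideation for "yes".
Treatments: ≥ 1 session/week (high or moderate activity), sitting
strictly below the cohort mean, or strictly below a threshold in
hours; an empty arm raises `PositivityError` naming the definition.

## Base learners and selection (`paxlearn.base_models`)

Six sklearn-backed candidates behind one interface; predicted
probabilities are clipped to `[1e-6, 1 − 1e-6]`. The network
configuration records the reference architecture (256-128-64 ReLU,
dropout 0.5, batch-norm, batch 64, lr 0.001, 50 epochs); the sklearn
`MLPClassifier` backend realises the architecture and optimiser but
substitutes L2 (α = 1e-4) for dropout/batch-norm, which it does not
support — recorded, not hidden. Selection scores holdout
Accuracy/AUC/F1 and picks the best mean rank, breaking ties by AUC
then candidate order.

## X-Learner (`paxlearn.xlearner`)

Standard three stages (see README). Numerical choices:

* propensities clipped to `[0.01, 0.99]`; perfect separation
  (in-sample AUC = 1) falls back to the constant arm share with a
  warning;
* a single-class arm in stage 1 uses a constant-probability fallback;
* stage-2 CATE components are clipped to `[−1, 1]` *before* the
  convex combination, so `min(τ₀,τ₁) ≤ τ̂ ≤ max(τ₀,τ₁)` and
  `|τ̂| ≤ 1` hold exactly;
* the 80/20 train/test split is stratified on treatment × outcome
  (falling back to treatment alone when a cell is too small).

## Inference (`paxlearn.inference`)

`ATE = mean(τ̂)` over the test split, `SE = sd(τ̂; ddof=1)/√n`, 95%
CI and two-sided p-value from the t distribution with n−1 degrees of
freedom; reported on the probability-reduction scale. Overlap
diagnostics flag runs with more than 10% of propensities outside
`[0.05, 0.95]`. The sitting-time sweep is an independent full
X-Learner run per threshold `h ∈ {4, 6, 8, 10, 12}`.

### Known limitation: the interval is anti-conservative

The SE above measures only the spread of the fitted per-unit effects
across test units. It omits the stage-1/stage-2 training noise, which
shifts *all* test-unit predictions together and dominates the
sampling variance of the ATE. The package's own calibration
diagnostic (`tests/test_acceptance.py::
test_type_i_error_of_the_nominal_interval_under_the_null`, also in
`scripts/acceptance.py`) quantifies this: under a zero effect with no
confounding (n = 2,000, 200 replicates), the nominal 95% interval
excludes zero in **67–75%** of replicates rather than 5%. At this n
the true sampling spread of the ATE is roughly 5–7× the reported SE.
The corresponding acceptance test is left failing deliberately: the
formula is implemented exactly as specified, and the failure
documents that it cannot be calibrated. Point estimates are
unaffected (mean absolute recovery bias < 0.01 at n = 20,000); only
interval coverage and significance claims are.

## Shapley importance (`paxlearn.importance`)

Built from first principles (no external SHAP dependency): exact
subset enumeration for ≤ 4 features (used as the oracle in tests —
additivity, null players and local accuracy hold to 1e-9), and a
sampled-permutation estimator otherwise (one background row per
(row, permutation), telescoping prefix predictions, single batched
model call). Importance is the mean absolute contribution over a row
subsample; defaults (background 100, permutations 200, 200 eval rows)
keep a 13-feature, ~6,600-row run under a few seconds.

## Problem sizes

All sizes are the package's own validation choices: n = 20,000 for
constant-effect recovery (Monte-Carlo error ≈ 0.004), n = 50,000 for
marginal fidelity (3·SE tolerances) and the 3%-treated rare-arm case,
n = 2,000 × 200 replicates for the type-I diagnostic, and the
21,508-row study emulation for the end-to-end scripts. The full test
suite runs in ~30 s; `scripts/acceptance.py` in ~15 s.
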