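# Methods

## The deployed-score model

The score under study is a frozen logistic regression on fully
dummy-encoded binary indicators: each covariate is a level of a categorical
(age band, lab-value band, utilization band, …) with an explicit reference
level, and missingness is itself an encoded level, so the design matrix has
no missing values by construction and no imputation happens at scoring
time. The raw prediction p = expit(β₀ + Σ βⱼxⱼ) is converted, separately
within each scoring year, into an integer percentile rank

    can_score = floor(100 · #{rows with strictly smaller p} / n) ∈ {0,…,99},

and the high-risk flag is `can_score ≥ t` (inclusive). Ranking per year is
deliberate: pooling years would let cohort-size changes in one year shift
another year's ranks. The strictly-smaller/floor tie rule means tied raw
probabilities share the lowest applicable rank (a panel of identical
probabilities scores 0 everywhere); whether a deployed system uses strict,
weak or averaged ranks only moves tied boundary cases, and the rule here is
pinned by tests.

## Performance metrics and their undefined states

Per year × threshold we tabulate TP/FP/TN/FN and derive TPR = tp/(tp+fn),
FPR = fp/(fp+tn), PPV = tp/(tp+fp), NPV = tn/(tn+fn),
accuracy = (tp+tn)/n, prevalence = (tp+fn)/n, and F1 = 2tp/(2tp+fp+fn),
which equals the harmonic mean of TPR and PPV whenever tp > 0 and stays
defined when that mean is 0/0. All these are ratios, so a confusion summary
may hold printed *proportions* instead of counts and give identical
metrics; this is how published classification-rate tables are re-analyzed.
A zero denominator makes a metric NaN — never 0 — and NaN propagates into
any drift delta built on it; a silent zero would fabricate drift.

Supplementary per-year diagnostics: rank-sum (Mann–Whitney) AUC with
half-credit ties, and calibration over ten equal-count deciles of predicted
probability (ties broken by stable input order; bin sizes differ by at most
one row). Equal-count deciles, not equal-width bins, match the "risk
decile" construction. Exact binomial CIs are Clopper–Pearson via beta
quantiles, with the conventional closed endpoints at k = 0 and k = n.

## Drift and the patient-level bootstrap

Drift is the signed change of a metric in percentage points, final year
minus baseline year of a period; the period label follows the
"scoring year (outcome-measurement year)" display convention. Affected
individuals are |ΔTPR| × final-year cases and |ΔFPR| × final-year controls,
rounded to whole persons; magnitudes are used only here, the drift tables
keep the sign.

CIs come from a nonparametric bootstrap whose resampling unit is the
patient: each replicate draws m patient ids with replacement and stacks all
their yearly rows (k draws → k copies of every row), preserving
within-individual correlation across years. Coefficients are never refit
inside a replicate; the percentile transform *is* recomputed per replicate,
so the score always ranks the replicate's own cohort — the internally
consistent choice when the ranking is part of the algorithm
(`drift_statistic` takes any metric subset, so the sensitivity of this
choice can be probed by passing a statistic that ranks once outside).
The CI is the (2.5th, 97.5th) percentile pair of the replicate
distribution. When m is smaller than the cohort, intervals are
conservatively wider; width shrinks like 1/√m (both verified by
simulation). A statistic that is NaN in more than 10% of replicates raises
rather than returning a quietly truncated interval. Default design:
m = 10 000 patients × 500 replicates — a desk-scale version of the
1 000 000 × 2000 design used against the full national cohort; both numbers
are configurable.

## Covariate shift, screening, ablation

Shift per binary covariate between years a and b is the standardized mean
difference with the pooled-Bernoulli-variance denominator,
SMD = (p_b − p_a)/√((p_a(1−p_a)+p_b(1−p_b))/2), the standard "table 1"
balance form; it is 0 by convention when both variances vanish, and
antisymmetric in its arguments (later minus earlier, matching the drift
sign convention). The screen flags |SMD| ≥ 0.1 (large shift) and/or
original OR ≥ 1.5 or < 0.5 (large effect); both cuts are configurable. The
screen is a pure threshold function — permutation invariant and idempotent
— and also emits the full SMD-vs-OR quadrant table per category for
plotting.

Ablation retrains by maximum likelihood (IRLS, deviance tolerance 1e-8,
≤ 100 iterations, deterministic) on the baseline year with flagged columns
dropped. Dropping one dummy level of a categorical silently redefines its
reference, so when a level-group mapping is supplied all sibling levels
leave together (a flag disables this). Rank-deficient designs fail naming
the collinear columns; separation and non-convergence fail with a
diagnostic. Comparison variants — original coefficients, flagged-excluded
refit, full-covariate refits on later years, optional per-category
exclusions — all run the identical score → rank → metrics → drift pipeline,
so the "original" variant reproduces the main drift table exactly.

## Quality-metric impact

Three endpoints per year × threshold, each with an exact binomial CI and
its numerator/denominator: (1) the quality metric, flagged patients with a
palliative-care visit / flagged; (2) false positives / flagged, which is
1 − PPV on the same rows (asserted as a cross-module identity); (3) false
positives among flagged patients with a visit / flagged with a visit, NaN
when no flagged patient has a visit. The visit flag is a per-year binary —
"had a first palliative-care visit that year" — with the identifier logic
that produces it considered upstream of the panel. The panel's single year
column is the only time axis; fiscal-vs-calendar subtleties are not
modeled.

## What the synthetic generator emulates — and what it does not

`generate_cohort` draws, per patient, a latent frailty term
N(0, frailty_sd²) once, reused every year as an additive logit offset —
this is what makes yearly outcomes positively correlated within patient
(verified by simulation; frailty_sd = 0 gives ≈ 0 correlation). Covariates
are redrawn each year as independent Bernoulli at that year's prevalence
(baseline unless a shift overrides it); mutually exclusive dummy-level
groups are drawn as one categorical with an implicit reference level. The
outcome follows the logistic model on covariates + frailty. When per-year
prevalence targets are set, the intercept is recalibrated by Brent root
finding on the realized linear predictors, so the expected prevalence
equals the target exactly and the realized one differs only by binomial
noise (an unreachable target raises rather than silently missing).
Palliative visits are Bernoulli with a two-parameter logistic link on the
outcome linear predictor (defaults −1.8 intercept, slope 1.0, giving ≈ 3%
visit rate among top-decile patients and a visit flag positively associated
with true risk — the level a flagged-denominator quality metric needs; no
generative detail for this mechanism is published, so the link is the
package's own choice).

The reference scenario (`default_scenario`): 200 000 patients × 5 scoring
years (2016–2020); 22 indicators across the five categories with an age
categorical as grouped dummies; outcome prevalence declining linearly
0.038 → 0.030 (the deployed cohort's decline was non-monotone with a
pandemic-era drop; the linear ramp isolates the prevalence mechanism);
frailty_sd 0.5; and prevalence shifts in the final two years confined to
utilization and laboratory/vital indicators plus one demographic priority
level, each with analytic |SMD| ≥ 0.12, while diagnostic and pharmacy
indicators stay at baseline. It does **not** emulate: correlation between
covariates (beyond level-group exclusivity), intra-year score updates,
patients entering/leaving the roster, time-varying coefficient
relationships (concept drift), or realistic code streams. Tests passing on
this cohort therefore demonstrate the pipeline's correctness and the
prevalence-mechanism arithmetic, not the magnitudes any real system would
show.

The recovery scenario (`recovery_scenario`) used for coefficient-recovery
checks is a single year at ~30% outcome prevalence with common covariates:
at a 3–4% outcome prevalence, the MLE standard error of a rare (4%)
indicator's log-odds at n = 100 000 is ≈ 0.09, so a ±0.05 recovery bound
would be noise-bound there; the moderate-prevalence design keeps every
standard error below 0.02 and makes the bound meaningful.

## Problem sizes and numerical choices

- Bootstrap coverage checks: 300 simulated cohorts of 10 000 patients,
  500 replicates each, target prevalence 0.038.
- Coefficient recovery: n = 100 000, tolerance ±0.05 log-odds.
- SMD recovery: reference scenario at n = 200 000; plug-in SMD within
  ±0.02 of the analytic value, unshifted covariates below 0.02.
- Intercept calibration: Brent on [−40, 40], xtol 1e-12.
- Refit determinism: repeated fits agree to < 1e-10.
- Report rounding: metrics to one decimal, classification rates and
  prevalences to two, counts as integers; the JSON bundle keeps full
  precision, and every CSV carries the run's config hash so report numbers
  trace to the exact configuration.

## Known limitations

- Covariate independence in the generator understates the joint
  (multivariate) shifts real utilization changes produce; the SMD screen is
  univariate by design.
- The percentile transform assumes each year's cohort is ranked in one
  batch; weekly or rolling scoring is out of scope.
- Bootstrap CIs are plain percentile intervals; no studentized or BCa
  variants.
- The ablation addresses covariate exclusion and re-training only;
  recalibration-style mitigations (Platt, isotonic) are out of scope since
  monotone output transforms cannot move a percentile-rank classification.
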