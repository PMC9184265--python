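# Methods

This note records the modelling assumptions, defaults and numerical
choices behind `bonedca`, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

Newly diagnosed prostate-cancer patients may receive a radionuclide bone
scan to detect skeletal metastases. Guidelines and published models
disagree about who to scan. The package compares staging strategies on
*net benefit* — a decision-analytic quantity that credits detected
positive scans and debits scans performed, weighted by a threshold
probability p_t expressing the decision-maker's conservatism/tolerance
trade-off — alongside classical external-validation metrics (calibration
slope, calibration-in-the-large, AUC). Scans within 140 days (20 weeks) of
diagnosis count as staging scans, with an inclusive boundary (a scan on
day 140 counts; the source convention gives weeks only, so the day-level
boundary is fixed here). Indeterminate scans are resolved by follow-up
labels where available; unresolved ones are treated as missing and
imputed.

## Synthetic registry generator

No population registry of this kind is publicly available, so the
generator emulates one with a known ground truth.

* **Predictors.** Age ~ N(67.9, 9²) truncated to [34, 98]. PSA is a
  lognormal mixture: 94% lognormal(μ=2.10, σ=0.55) (median ≈ 8 ng/mL) plus
  a 6% metastatic-like tail lognormal(4.0, 0.9), giving the heavy right
  tail real registries show. Gleason patterns, T-stages and the
  beta-distributed percent positive cores follow categorical/beta
  marginals chosen to match a population registry: ≈36% Gleason ≤6, ≈27%
  3+4, ≈16% 4+3, ≈21% ≥8; ≈64% T1, 29% T2, 5% T3, 3% T4; cores median
  ≈33%.
* **Latent positivity.** log-odds(positive) = β₀ + 1.10·ln PSA +
  0.55·(grade group − 1) + 0.22·T-index + 0.008·%cores. The intercept β₀
  is calibrated at generation time (Brent root-finding on the drawn
  sample) so the mean risk among scanned patients equals the target
  positivity, default 8.7%. Coefficients live in `GeneratorConfig`, not in
  code. Scan sensitivity/specificity are perfect apart from an
  indeterminate rate (3.7% of performed scans), a simplification: real
  bone scans have substantial false-positive rates.
* **Scan availability (the outcome-missingness mechanism).** The
  probability that a staging scan result is on record depends on a
  three-level risk stratum (computed from true predictor values) and on
  treatment setting, e.g. 62% for high-risk public patients vs 10% for
  low-risk private ones, averaging ≈38% scanned. This encodes the two
  mechanisms a registry exhibits — selective scanning of higher-risk
  patients and restricted data access for privately treated patients —
  and makes the scan outcome missing at random given predictors, setting
  and survival.
* **Predictor masking.** Per-variable MAR masking with marginal rates
  40.1% (PSA), 76.6% (T-stage), 2.4% (Gleason), 17.1% (cores), 76.0%
  (nodal stage), tilted toward private-setting and low-risk patients by
  multiplicative factors and renormalised so the configured rate *is* the
  marginal rate.
* **Survival.** Exponential, 0.0021/month for scan-negative patients
  (5-year survival ≈ 88%) with hazard ratio 5.5 for scan-positive (≈ 50%),
  administratively censored at the study horizon. Chosen so the
  Kaplan–Meier congeniality diagnostic has signal; no attempt at
  cause-specific mortality.
* **Determinism.** One master seed, split into named substreams
  (predictors / scan assignment / survival / masking), so identical
  configs are byte-identical and stages are independently reproducible.

What passing tests on this generator show: the pipeline's statistical
machinery is correct under a congenial MAR mechanism. What they do not
show: robustness to MNAR missingness, measurement error in predictors,
imperfect scan accuracy, or joint-distribution features of any real
registry beyond the marginals above.

## Risk models

Eleven models are registered with their published rules read literally
(">" strict, "≥" inclusive): three continuous (Chybowski, Ho, Wang), five
categorical (Briganti, Cambridge/Gnanapragasam, ISUP, Lai, O'Sullivan) and
three guideline stratifications (AUA 2018, EAU 2020, NCCN 2019). Points of
note:

* **Wang.** D = −6.40 + 2.39·[T4] + 0.87·ln(PSA+1) + 0.93·[GS ≥ 4+3] +
  2.169; probability = logit⁻¹(D). The published decision rule "scan when
  D < 0" points opposite to the score's risk-increasing coefficients; it
  is implemented exactly as printed, with an `invert` flag for users who
  believe the intended direction was the reverse. The discrimination score
  is D itself, so AUC is unaffected by the rule's direction.
* **Cambridge grouping.** Tiers 3 and 4 follow the published strategy
  boundaries; the group-5 criteria (grade group 5, T4, or two of
  {grade group 4, PSA > 20, T3}) come from the model's source study and
  are overridable (`group5_rule`), being externally sourced.
* **EAU high-risk-only** is encoded as PSA > 20, GS ≥ 8 or T ≥ T3a —
  strictly nested inside the full EAU rule (which also scans Gleason 4+3
  intermediate-risk disease).
* **Briganti "T2-3"** is read as T2a–T3c inclusive.
* **Continuous forms for Ho and Chybowski** are not published in usable
  form here; they are config-supplied (logistic coefficients / PSA-to-risk
  lookup table). Requesting a probability form that is not configured is
  an explicit error, never a silent fallback.
* **Per-group development positivity rates** (used as predicted risks for
  categorical-model calibration) are configuration. Defaults carry only
  each model's overall development rate, so categorical models are
  excluded from calibration out of the box — mirroring the fact that
  meaningful rates must come from each development study. Guideline
  strata have no numeric risks at all; their AUC uses the group-ordinal
  rank as score.
* **PSA density** (AUA/NCCN very-low vs low split) is omitted: the split
  does not change the bone-scan recommendation.

## Imputation

Chained equations with type-matched conditionals: type-1 predictive-mean
matching (k = 5 donors, Bayesian parameter draw) for continuous (log PSA,
% cores) and ordinal (grade group, T-stage index) variables; Bayesian
logistic draws for binary ones (nodal stage, scan positivity), falling
back to a flagged marginal draw if a conditional fit degenerates. Every
conditional model sees age, treatment setting, diagnosis year, the other
disease factors and survival encoded as (log(1+t), event) — the variables
the MAR argument rests on. Visit order is increasing missingness, ties
alphabetical. Imputed grade groups decode to representative Gleason
patterns (1→3+3 … 5→4+5).

Reference scale is m = 100 datasets × 100 iterations; the package default
and all tests/examples run m = 5 × 10 iterations, a scale this package
adopts because the chained-equations sweep mixes within a few iterations
on these data and the recovery experiments already cover the truth at
m = 5. Pooling uses Rubin's rules (total variance = within + (1+1/m)·
between; large-sample df, Barnard–Rubin adjustment when a complete-data df
is supplied). The Kaplan–Meier diagnostic contrasts observed-positive vs
imputed-positive (and negative) strata; with a hazard ratio of 5.5 in the
generator, congenial imputation reproduces the separation in the imputed
strata.

## Validation metrics

* Predicted risks are clipped into (10⁻⁶, 1−10⁻⁶) before the logit.
* Calibration slope/intercept come from statsmodels GLM fits; constant
  predictions or single-class outcomes raise an explicit error.
* Calibration requires at least four distinct predicted-risk levels —
  two- and three-group models cannot support a meaningful slope.
* AUC is the Mann–Whitney rank statistic (ties half) with DeLong placement
  variance; it is pooled on the raw scale across imputations. Logit-scale
  pooling was considered and not adopted: at AUC ≈ 0.7 with these sample
  sizes the difference is far below the pooled SE.

## Decision curves

* Grid p_t 0.01–0.10, step 0.001; both ends inclusive.
* Continuous models scan at predicted risk **≥** p_t (inclusive).
* NWT is displayed as ⌊1/p_t⌋ (with a 10⁻⁹ guard against float noise at
  exact reciprocals), which reproduces every conventional printed boundary
  (100, 40, 33, 14, 13, 10).
* Curves pool across imputations by the simple mean — counts are linear
  in datasets, so mean-of-NB equals NB-of-mean-counts.
* The optimal-strategy map breaks net-benefit ties toward the strategy
  scanning fewer patients (at equal NB, scanning burden is the only
  differentiator), then alphabetically for full determinism.
* `recommended_vs_best_table` compares each model's source-recommended
  strategy with the best in-model alternative (its other registered
  strategies, plus every grid threshold when a probability form exists);
  a mis-calibrated continuous model is typically beaten somewhere on the
  grid by its own fixed cut-off, which is the qualitative signature the
  mis-calibration experiment in the test suite reproduces with a known
  odds distortion.
* Reporting percentages round half-up to one decimal; a truncation flag
  exists because one conventional figure (3.6% for 150/4079) is a
  truncation, not a rounding.

## Degenerate inputs and numerical conventions

* Generator: probabilities outside [0,1], non-positive n, or an
  uncalibratable intercept raise configuration errors; an intercept of −∞
  is allowed and yields zero positives.
* Staging window: negative scan offsets are data errors.
* Net benefit: n = 0, p_t outside (0,1), or inconsistent counts raise.
* Rubin pooling with m = 1 returns the single dataset's estimate with
  infinite df.
* PMM donor search uses a sorted 2k-neighbour window (O(n log n)), an
  exact k-nearest match on the linear predictor scale.

## Known limitations

* Real-registry results are not reproducible here: the validation cohort
  behind the published strategy ranking is not public, so all quantitative
  claims are about the synthetic system; only qualitative patterns (e.g.
  scan-all dominating at conservative preferences, selective rules at
  tolerant ones) transfer.
* The generator draws predictors independently apart from the structure
  induced by the latent model and stratum-based masking; real registries
  have stronger predictor correlations (e.g. PSA with T-stage).
* No MNAR sensitivity analysis; no confidence bands on decision curves;
  no cost-effectiveness layer; plotting is intentionally out of the tested
  surface (all outputs are data tables).
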