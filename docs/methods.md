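# Methods

## Scope and data model

The package operates on patient-level tables of an acute-ischemic-stroke
cohort: demographics, admission NIHSS (0–42), coded imaging findings, acute
treatment flags (IV tPA, endovascular therapy) and the 6-month modified
Rankin scale (0–6).  Imaging arrives pre-coded — CTA occlusion sites from
{distal ICA, MCA M1, MCA M2, basilar, other} and NCCT hypodensities as a
subset of the ten ASPECTS regions plus two bilateral posterior flags — so no
image processing of any kind is involved.  Records lacking a reliable mRS
or NIHSS are excluded (with counts by reason) before analysis; death
(mRS 6) is a valid outcome and counts as poor under the mRS > 2 dichotomy.

The cohort file dialect is deliberately rigid: comma-separated UTF-8 with a
mandatory header, `;`-joined tokens inside list-valued cells in a fixed
canonical order, booleans as `0`/`1`, missing values as empty cells, and
floats written in shortest-exact-repr form.  This makes `read ∘ write` the
identity byte-for-byte on canonical files, which the tests rely on.

## Instruments

* ASPECTS score = 10 − |distinct hypodense anterior regions|; ≤ 7 is major.
  ASPECTS is applied uniformly to all patients; a purely posterior stroke
  has no anterior hypodensities and scores 10.
* BASIS is major on (qualifying occlusion) ∨ (ASPECTS ≤ 7) ∨ (bilateral
  pons hypodensity) ∨ (bilateral thalamus hypodensity).  "Other" occlusions
  never qualify, any M2 occlusion qualifies, and unilateral pons/thalamus
  findings have no effect.  Because the parenchymal criterion is shared,
  ASPECTS-major ⇒ BASIS-major for every possible finding — the test suite
  verifies this exhaustively over all 2^10 region subsets × occlusion-site
  subsets × flag combinations, along with monotonicity (adding a finding
  can never demote BASIS).
* NIHSS is major strictly above 10; 10 itself is non-major.
* The combined instrument is the obvious three-way partition of the
  NIHSS × BASIS dichotomies.

## Evaluation statistics

All evaluation machinery is implemented from counts upward; scipy supplies
only reference distributions (normal, χ², t, binomial) and midranks.

* 2×2 convention: rows predicted major/non-major, columns poor/good.
  Proportion CIs are Wilson score intervals (good coverage at small
  counts; the degenerate ends k = 0, k = n are clamped to 0 and 1).
* Odds ratios use the cross-product estimate with the Woolf log-normal 95%
  interval at z = 1.96; any zero cell triggers the Haldane–Anscombe +0.5
  correction on all four cells, flagged in the result.
* McNemar: exact doubled-tail binomial p (capped at 1) when the discordant
  total b + c ≤ 25, otherwise the continuity-corrected χ² on 1 df; b + c = 0
  returns p = 1 with a degenerate flag.  The exact branch is verified
  against rational-arithmetic binomial enumeration for every split up to
  the threshold.
* Pearson r×c χ² with df = (r−1)(c−1), no continuity correction (optional
  Yates for 2×2); zero marginals are an error.
* Wilcoxon rank-sum: midranks, tie-corrected null variance, two-sided
  normal approximation without continuity correction; the statistic and
  both null moments are checked against exhaustive permutation enumeration
  on small samples.
* Welch t with Satterthwaite df, also available from summary statistics
  (mean, SD, n) so published group summaries can be re-tested.
* Report-time percentages use half-up rounding to one decimal — the
  convention of printed clinical tables and the reason the reproduced
  accuracy table matches the published one cell-for-cell.  Internal values
  keep full precision.

Logistic regression is Newton–Raphson / IRLS on the Bernoulli
log-likelihood, starting from zero, converging when both the log-likelihood
change < 1e-8 and the score norm < 1e-8 (max 100 iterations); standard
errors come from the inverse observed information.  Requiring the gradient
condition as well as the likelihood condition makes the single-binary-
covariate identity (slope = log sample odds ratio) hold to 1e-8, which the
tests assert.  Coefficients exceeding magnitude 30 raise a separation
error; rank-deficient designs raise a collinearity error.  Stepwise
selection is likelihood-ratio based with p-to-enter 0.05 and p-to-remove
0.10 iterated to a fixpoint; since p-to-enter < p-to-remove the procedure
cannot oscillate, and every add/drop decision is recorded with its p-value
in a selection trace.  No Firth correction, exact logistic regression, or
multiple-testing adjustment is provided.  Interaction terms can be added by
the caller as product columns; no default interaction set is claimed.

## The published-count audit

Only summary counts of the 649-patient cohort were published, but they pin
down each instrument's 2×2 table exactly: e.g. for the dichotomized NIHSS,
tp = 138, fp = 188 − 138, fn = 253 − 138, tn = 396 − 50.  The fixture layer
(`strokeclass.stopstroke`) encodes the printed counts, rebuilds every table
with hard margin checks (any mismatch aborts the build), and re-derives the
published accuracy table, stratum proportions, subgroup rates and the
concordant-stratum odds ratio 12.6 (7.9–20.0).

Three published inconsistencies are encoded honestly rather than resolved:

1. the running text's ASPECTS sensitivity "30.8% (78/253)" conflicts with
   the accuracy table's 30.0/62.8 pair, which jointly force tp = 76; both
   variants are kept and each drives the target it supports;
2. the published discordant-stratum odds ratio 5.4 (3.5–8.5) is not the
   crude value implied by the reconstructed strata (4.6); it is reported
   with a discrepancy flag, never asserted;
3. the occlusion subgroup is printed as "of the 253 BASIS+ patients, 200
   had arterial occlusions" although BASIS-major n = 249; the subgroup uses
   200/126 as printed.

The published multivariate coefficient table and the McNemar p-values
comparing instruments require patient-level paired data that was never
deposited; they are deliberately not reproduction targets.  The fitting and
testing machinery itself is instead validated by oracles and simulation.

## Synthetic cohort generator

The generator emulates the joint structure the analysis assumes, in causal
order: age ~ N(68.2, 15.4²) (clipped at 1, rounded to 0.1 years), sex and
comorbidities as independent Bernoullis at the cohort rates, a qualifying
occlusion with probability 200/649 (site mixture ICA 0.20 / M1 0.40 /
M2 0.30 / basilar 0.10 — unreported in the source, configurable), atrial
fibrillation conditional on occlusion (0.337 vs 0.155, solved so both the
overall 137/649 and the BASIS-major 75/249 enrichment hold), a hypodense
region count K (zero-inflated shifted Poisson: lesion probability 0.65/0.30
and rate 1.97/1.19 given occlusion/no occlusion, regions sampled uniformly
without replacement, capped at 10), bilateral posterior flags at 0.005
each, admission NIHSS, treatments, and outcome.  Hypertension has no
published rate in the source's demographics table; 0.60 is used as a
typical ischemic-stroke cohort prevalence.

NIHSS is a discretized log-normal `round(exp(N(log m, σ)))` clipped to
0–42, conditioned on severity: m = 13, σ = 0.50 with a qualifying
occlusion; m = 8.5, σ = 0.75 with parenchymal findings (any hypodensity or
posterior flag) but no occlusion; m = 2.5, σ = 0.55 with clean imaging.
These values were derived analytically so that the population medians are
5 overall, 12 in BASIS-major and 3 in BASIS-minor, and P(NIHSS > 10) =
0.2897 = 188/649.  The zero-inflated-Poisson parameters analogously give
P(ASPECTS-major) = 0.1866 ≈ 121/649 and P(BASIS-major) = 0.3836 ≈ 249/649.

Outcome is drawn from a logistic model on [NIHSS > 10], [BASIS-major] and
age in years (β_age = log 1.05 per year by default).  The remaining three
coefficients are solved at run time inside `default_params()`:
the poor-outcome probability of a stratum, integrated over age by 80-node
Gauss–Hermite quadrature, is matched by root bracketing to the published
conditional rates 114/147 (concordant-major) and 77/358 (concordant-minor),
and the NIHSS/BASIS split of the remaining effect is solved so the overall
rate is exactly 253/649 given the analytic stratum weights.  The defaults
stored on `GeneratorParams` are the same solved values (intercept −4.770,
β_NIHSS 2.088, β_BASIS 0.737); overriding structural parameters far enough
that the published rates become unattainable silently keeps the stored
coefficients.  mRS within the poor/good bands is uniform ({3..6} / {0..2})
because only the dichotomy is analyzed.  Treatment assignment is
descriptive, not causal: IV tPA at 64/188 vs 37/461 by NIHSS class, and
endovascular therapy only in BASIS-major patients (29/147 concordant-major,
2/102 BASIS-only), mirroring the cohort's treatment pattern.

`calibration_report` compares a generated cohort against all thirteen
calibration targets: proportions within 3 binomial standard errors at the
realized denominator, the age mean within 3 SEM, and the three NIHSS
medians within one point (a discrete median has no binomial SE; at the
default parameters the population medians sit far enough from the adjacent
integers that n = 20000 draws virtually never miss them).

What the generator does *not* model — and hence what passing tests do not
establish about real data: site/hospital effects, time from onset, imaging
timing, correlated comorbidities beyond atrial fibrillation, treatment
effects on outcome (treatment is assigned but does not enter the outcome
model, matching the published finding that prediction held "regardless of
treatment"), measurement error in instrument coding, and any joint
NIHSS–occlusion structure beyond the three severity classes.  The
generator's match to the published marginals shows the pipeline is
correct, not that the biological model is.

## Problem sizes and seeds

Simulation-backed checks use n = 20000 for calibration (binomial SEs small
enough to resolve the designed gaps), 50 replicates at n = 5000 for
logistic parameter recovery (each coefficient within 3 SEs, ≥ 90% of
replicates), and 100 replicates at n = 2000 for stepwise noise exclusion
(≥ 95%).  The noise-exclusion property deserves a caveat: under the null
the likelihood-ratio p-value is approximately uniform, so with p-to-enter
0.05 the expected exclusion rate is itself ~95%, and any single 100-
replicate batch has material probability of landing a point or two either
side; the fixed seeds used here realize 96–98%.  All randomness flows
through `numpy.random.default_rng` seeds carried in `GeneratorParams` or
passed explicitly; the same seed reproduces a cohort byte-identically.

## Known limitations

* The posterior-circulation BASIS criterion implements only the stated
  bilateral pons/thalamus rule; the original scale's fuller posterior
  criteria are out of scope.
* The rank-sum and McNemar large-sample branches are asymptotic; no exact
  permutation p-values are returned (the oracles enumerate them only to
  validate moments and the exact-binomial branch).
* Stepwise selection inherits the usual caveats of data-driven selection;
  the trace exists precisely so users can audit it.
* The definition of an "unreliable" mRS/NIHSS in the source cohort is
  unknown; the cohort model represents only missingness.
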