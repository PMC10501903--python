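# Methods

## The model and the workflow

The target condition is amyloid-β (Aβ) pathology in patients with mild
cognitive impairment, indexed by a binary Aβ-PET status. Step 1 is an
ordinary maximum-likelihood logistic regression,

    logit P(Aβ+) = β₀ + β₁·log(p-tau217) + β₂·age + β₃·APOEε4,

with plasma p-tau217 entered on the natural-log scale (its distribution is
strongly right-skewed and strictly positive) and age linear. The natural
log is used throughout; any other base would only rescale β₁. Predicted
probabilities are cut at two thresholds into low / intermediate / high risk
zones; step 2 classifies the intermediate zone by a confirmatory binary
test (CSF Aβ42/Aβ40 by default — any binary column can be supplied, which
also covers comparisons of alternative confirmatory markers). Low-zone
patients are called Aβ-negative, high-zone Aβ-positive, so overall accuracy
decomposes exactly into correct-low + correct-high + correct-confirmatory
over N, and the tests-avoided fraction is the low+high share of the cohort.
Both identities are enforced as dataclass invariants, not just tested.

Assumptions worth keeping in mind: complete predictor and confirmatory
availability (complete-case filtering is explicit and counted), a binary
confirmatory test already cut at its own threshold, and no re-use of the
confirmatory marker inside the risk model.

## Model development and internal validation

*Variable selection.* Backward elimination runs inside a bootstrap
(default n_boot = 1,000): each resample (drawn with replacement at the
original size, redrawn if single-class) gets a full-model fit followed by
iterative deletion of the predictor with the largest Wald p-value ≥ α,
with α = 0.157 by default (the conventional stopping criterion for
model-development settings, approximately equivalent to AIC-based
selection). The spec of the statistic is a package choice: Wald p-values
are the conventional fast-backward criterion; a likelihood-ratio variant
was considered and rejected as ~3× the cost for near-identical paths at
these sample sizes. Subset frequencies are reported; the modal subset wins,
with ties broken toward the larger subset (conservative retention).

*Optimism correction.* Harrell's bootstrap: for each resample, fit (with
optional re-selection via the `reselect` flag, exposing both readings of
"selection during bootstrapped internal validation"), then
optimism_b = AUC(resample model on resample) − AUC(resample model on the
original data); the corrected AUC is the apparent AUC minus the mean
optimism. A known property of this estimator, reproduced by an independent
sklearn-coded oracle in development: in heavily overparameterized null
designs (e.g. 20 noise predictors at n = 100) it removes most but not all
of the inflation, leaving the corrected AUC several points above chance.
The package reports the estimator as defined rather than silently
substituting a different one (0.632+ would behave better there but is a
different method).

*Discrimination and fit.* AUC is the Mann–Whitney pairwise concordance
with ties counted ½, computed via midranks; its CI is DeLong's
large-sample interval (the CI method is a package choice; printed CIs are
therefore not expected to match other software to the decimal). Nagelkerke
R² and AIC come from the same likelihood; calibration uses decile bins of
predicted probability with empty bins (from heavy ties) merged and logged.

*Separation.* Quasi-complete separation is detected by non-convergence or
any |coefficient| > 40 on the logit scale and raised as an estimation
error naming the diverging predictor; bootstrap resamples that fail are
excluded and counted.

## Threshold derivation

Candidate thresholds are the observed predicted probabilities. The lower
threshold is the largest candidate keeping sensitivity (share of true
positives at or above it) ≥ the target; the upper threshold is the
smallest candidate keeping specificity (share of true negatives below it)
≥ the target. Achieved metrics therefore meet or exceed their targets by
construction — printed sensitivities are floors, not nearest-to-target
values. Zones are half-open: low is p < lower, high is p ≥ upper,
intermediate is [lower, upper). Two edge conventions are the package's own:

- if no observed probability reaches the specificity target (the largest
  probability belongs to a negative), the grid is extended by the midpoint
  between max(p) and 1, giving an empty high zone rather than an error;
- if the independently derived thresholds cross (lower > upper — which
  happens when the model separates the classes so well that both targets
  are achievable at one cutoff, the limit being perfect separation), they
  collapse to the single grid cutoff that meets both targets with maximal
  combined sensitivity + specificity. The choice is target-independent, so
  the cross-stringency monotonicity (lower non-increasing, upper
  non-decreasing, intermediate zone non-shrinking as targets rise
  90 → 95 → 97.5) survives the collapse. A degenerate-threshold error
  remains for the case where no single cutoff meets both targets, which
  cannot occur under this grid convention but is kept defensively.

An optional display mode rounds thresholds to integer percentages the
conservative way (floor for lower, ceil for upper) so that achieved
sensitivity/specificity still meet their targets; analysis defaults are
unrounded.

All proportion CIs (zone NPV/PPV, confirmatory PPV/NPV, overall accuracy)
are two-sided 95% Wilson score intervals.

## Gaussian-mixture binarization

Continuous PET SUVr and CSF Aβ42/Aβ40 are binarized by a univariate
two-component Gaussian mixture fitted with EM: median-split
initialization, tolerance 1e-8 on the log-likelihood, at most 500
iterations, no random restarts — fully deterministic. The cutoff is the
point between the component means where the weighted densities cross
(equal posterior membership), solved in closed form from the quadratic in
x; the mixture-to-cutoff rule is recorded on every cutoff object because
published cutoffs do not always state which rule produced them, and a
"normal-component mean ± k·SD" alternative is available but off by
default. Boundary values count as positive in both directions, matching
the ≥ / ≤ notation of printed cutoffs. On effectively unimodal input the
EM legitimately ends at the iteration cap with heavily overlapping
components; the overlap is logged and the non-converged flag blocks cutoff
derivation.

## The synthetic cohort generator

The generator emulates the joint structure the analysis needs, not any
particular patient population: Aβ-PET status is Bernoulli (default
prevalence 0.60, echoing memory-clinic MCI cohorts); p-tau217 is
log-normal conditional on status, parameterized by the Aβ-negative
arithmetic mean/SD (defaults 0.153 / 0.077 pg/ml, the scale of published
cognitively-unimpaired Aβ-negative reference samples) and a geometric-mean
fold-change (default 3.0, the magnitude reported for p-tau217 assays);
APOE ε4 is Bernoulli by status (defaults 0.35 / 0.70); PET SUVr and the
CSF ratio are per-status Gaussians whose defaults put the mixture cutoffs
near published values (≈1.14 SUVr, ≈0.066 ratio); binary CSF status agrees
with PET with probability 0.90 (a single global concordance — real
discordance is concentrated near cutoffs, which the generator does not
model); and a second assay is the same analyte times a scale factor with
multiplicative log-normal noise (CV default 0.05). Age is drawn
independently of status by default because no joint distribution is
published; an `age_beta` flag adds a log-odds-per-year dependence and is
used wherever a test needs age to carry real signal. All draws flow from a
single seed through separated streams (cohort vs reference samples), so
identical configs reproduce byte-identical CSVs.

What passing tests on this generator do *not* show: robustness to
comorbidity effects on p-tau217 (renal function in particular), batch or
drift effects beyond a global scale, non-Gaussian marker tails, or
covariate-dependent CSF/PET discordance. Results on synthetic cohorts
demonstrate the machinery and its identities, not clinical performance.

Default fixture sizes: n = 348 single-cohort, or 136 development + 212
validation in two-cohort mode, with n_boot = 1,000 — the full pipeline
runs in ~10 s on one CPU. Heavier simulations in the test suite use
n = 20,000–50,000 where parameter-recovery or marginal checks need them.

## z-score harmonization

z = (x − mean_ref)/sd_ref against a cognitively-unimpaired Aβ-negative
reference sample, supplied as a summary (n, mean, SD) because laboratories
hold reference distributions as summaries; a helper computes one from raw
values. In the z-model the p-tau term enters *linearly* (z-scores can be
negative), a deliberate structural change from the log-concentration
model; empirically the two models' discrimination agrees within a couple
of AUC points on the default fixture. Transfer applies the z-model
coefficients and the original thresholds unchanged to an external cohort
z-scored against its own reference. References below n = 50 trigger a
warning (published references run 111–316). Mis-calibrated references
(e.g. a mean shifted by +2 SD) measurably degrade the low-zone NPV — the
negative control in the test suite.

## Known limitations

- Single global CSF/PET concordance in the generator (see above).
- The optimism bootstrap's residual bias in extreme p/n regimes is a
  property of the estimator, documented rather than patched.
- No penalized or Firth regression, interactions, or splines; no
  cost-weighted threshold optimization; no assay bridging beyond
  z-scoring (no Deming/Passing–Bablok regression); no centiloid handling.
- Printed integer thresholds in published tables may be display rounding;
  the package defaults to unrounded thresholds and offers conservative
  rounding only as a display mode.
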