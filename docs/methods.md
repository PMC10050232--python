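# Methods

## Generative model

Each simulated patient carries a binary biomarker `M ~ Bernoulli(prevalence)`
and a latent event time that is exponential with a median specific to the
(biomarker, treatment) cell, `T | M=m, X=x ~ Exp(ln 2 / median(m, x))`,
independent of everything else. All times are in months. The default cell
medians are 9 (positives on A), 9 (positives on B), 9 (negatives on B) and
12 (negatives on A); the study grid varies the positives-on-B median over
{9, 12, 21} and the prevalence over {0.25, 0.50}. The defaults encode the
ideal-physician null: the physician's-choice arm reproduces the directed
strategy exactly, so true clinical utility is zero in every grid scenario
while the experimental contrast's truth is not.

Accrual is uniform on `[0, accrual_duration]` (default 0, i.e. instantaneous
enrolment) and follow-up ends administratively at calendar time
`admin_censor_time` (default 60). Censoring therefore depends only on entry
time — completely independent censoring, the condition under which the
pseudo-observation estimating equations are consistent. With the default
medians this censors roughly 1–14% of events depending on the cell. No other
censoring mechanism is modelled (deliberately: informative or
covariate-dependent censoring is out of scope).

Enrolment size is `2 * n_per_arm` patients (default 500 per arm). The
enrichment design screens Bernoulli(prevalence) candidates and enrolls only
positives, so prevalence still governs the screening burden; the cohort
itself contains exactly the target number of positives.

What the generator does **not** emulate: non-exponential hazards
(non-proportional subgroup hazards, cure fractions), covariates beyond the
biomarker, staggered-entry analyses before the final horizon, dropout, or
measurement error in the biomarker assay. Passing tests therefore
demonstrate the estimators' behaviour under proportional exponential
hazards with independent censoring, not robustness to violations of those
assumptions (the pseudo-observation estimands remain valid without
proportional hazards, but the simulations here do not exercise that).

## Designs and identifiability

Randomization probabilities default to 1:1 everywhere
(`r_strat = r_pos1 = r_neg1 = r_pos2 = r_neg2 = 0.5`), standard confirmatory
practice. Arm labels are fixed strings (`directed`, `physician`,
`randomized`, `A`, `B`). The physician arm of the strategy design uses the
biomarker only to generate outcomes; it is recorded as unmeasured and is
blanked in exported CSVs, mirroring the information actually available in
such a trial. The same applies to the randomized arm of the modified design
when `test_marker_in_randomized_arm` is false.

Identifiability is enforced as a total gate: every (design, contrast) pair
either estimates or raises `IdentifiabilityError`. The modified design
without biomarker testing identifies neither subgroup-conditional summary,
but its directed-vs-randomized comparison is still directly observed; the
package exposes that experimental-utility comparison with a warning rather
than suppressing it, since the literature is ambiguous on whether to count
it as "identified".

The matching formula `r_pos1 = r_strat + (1 − r_strat)·r_pos2` equates the
positive stratum of a stratified design with the modified design. For the
negative stratum the directed arm assigns treatment A, so the same formula
applies to the probability of A: `r_neg1 = 1 − [r_strat +
(1 − r_strat)(1 − r_neg2)] = (1 − r_strat)·r_neg2`. `matched_stratified_design`
packages both.

Experimental clinical utility on a *stratified* cohort (no arms to compare)
is estimated by an independent random half-split: each patient goes to a
directed-evaluation pool — kept only when the randomized treatment agrees
with the strategy rule — or to a randomized-evaluation pool, kept always.
Because the split is independent of outcomes, the pools are unbiased,
disjoint samples of the two counterfactual arms and the ordinary two-arm
estimators apply; the price is efficiency, not bias. The engine's canonical
route for this contrast is a modified biomarker-strategy trial.

## Estimators

- **Kaplan–Meier** uses the standard convention that a censoring tied with
  an event is ordered after it. Evaluation beyond the last observed time
  carries the last value and warns (deterministic, and rare at the default
  sample sizes). RMST is the exact area under the step function.
- **Logrank** is the (O−E)²/V chi-square with the hypergeometric variance at
  each distinct event time. On tie-free two-group data it equals the Cox
  score statistic; the tests assert agreement to 1e-6.
- **Cox regression** maximizes the Efron-tied partial likelihood by Newton's
  method with step-halving (tolerance 1e-10 on the step, max 50 iterations).
  Continuous simulated times are tie-free almost surely, but CSV round-trips
  can create ties, hence Efron. Fits with any |log HR| > 20 are rejected as
  complete separation (a compared group with no events) and the replicate is
  recorded as non-estimable rather than imputed. Wald tests are used for all
  Cox and pseudo-value coefficients, matching the "coefficient = 0" null
  statements of the model parameterizations.
- **Pseudo-observations** are exact jackknife values of the *pooled*
  (covariate-ignoring) Kaplan–Meier functional — the standard
  Andersen/Klein construction; per-group computation is available as a
  non-default option (`groups=` in `PseudoValueRegression.fit`). Rather than
  refitting KM n times, the implementation uses closed-form leave-one-out
  updates: removing subject i shrinks every risk set at times ≤ Tᵢ by one
  (and the death count at Tᵢ if i is an event), so each leave-one-out curve
  is a product of two precomputed prefix products. The whole vector costs
  O(n log n). Degenerate corner cases (e.g. a lone subject at the last
  event time) fall back to a literal leave-one-out recomputation; the test
  suite checks the fast path against a brute-force oracle to 1e-10,
  including tied and heavily censored samples.
- **Identity-link regression** of pseudo-values is ordinary least squares
  with a robust sandwich variance (bread `(ZᵀZ)⁻¹`, meat `Σ Zᵢ rᵢ² Zᵢᵀ`);
  pseudo-values are not independent given the pooled estimate, so the
  model-based variance would be wrong. Rank-deficient design matrices raise
  an error naming the collinear columns.

The SD/RMST horizon defaults to t = 36 months, inside the follow-up for
every grid scenario (survival at 36 months ranges from about 0.06 to 0.30
across cells). All tests are two-sided at α = 0.05.

## Monte-Carlo engine

Replicate k draws its generator from
`SeedSequence(entropy=seed, spawn_key=(k,))`, so each replicate is
reproducible in isolation and results are independent of execution order.
Within a replicate, one trial is generated per design required by the
requested contrasts — a strategy trial for the comparative contrast and a
modified-strategy trial for the experimental contrast — sharing the scenario
parameters but not patients. Non-estimable replicates (separation, no
events) are dropped with a logged count; none occur at the default sample
sizes. Operating characteristics report rejection rates, mean estimates,
empirical SDs, bias against the analytic truth and Monte-Carlo standard
errors throughout. For hazard ratios the engine records the mean on both
orientations (directed-coded, and its reciprocal), since the two differ
under the experimental contrast and reporting conventions vary.

The six-scenario experiment uses 1000 replicates of 500 patients per arm per
scenario, which runs in about two minutes on one CPU and puts the
Monte-Carlo SE of a 0.05 rejection rate at ≈ 0.007 and of the mean RMST
difference at ≈ 0.026 months.

## Analytic truths

`true_contrast_value` evaluates the generative truth in closed form:
subgroup HRs are ratios of exponential rates (equivalently inverse ratios of
medians), SD and RMST truths are differences of `e^{−λt}` and
`(1 − e^{−λt})/λ` mixed over the biomarker distribution and the assignment
law of each arm. Mixtures of distinct exponentials do not have proportional
hazards, so a scalar HR truth exists for the utility contrasts only when the
two compared populations coincide (then HR = 1, as under the ideal
physician); otherwise the HR request raises rather than returning a
pseudo-truth.

## Known limitations

- Two treatments, two subgroups; the interfaces do not generalize to more
  arms without extension.
- Only exponential event times are generated (the estimators themselves are
  distribution-free).
- The experimental-contrast cells of the six-scenario grid depend on design
  settings (per-arm n, censoring, horizon) that are scenario choices of this
  package; they demonstrate the qualitative inflation of the apparent type I
  error, and their magnitudes move with those settings.
- No proportional-hazards diagnostics are provided; HR estimates under
  non-proportional alternatives are reported as fitted, without warning.
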