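# Methods

## The behavioral model

`rewardtask` analyses (and simulates) the cued reward-size task used to
index motivation in macaques. On each trial a visual cue announces how many
drops of liquid reward (R ∈ {1, 2, 4, 8}; one drop ≈ 0.1 ml) a correctly
timed bar release will earn. Releases between 200 and 1000 ms after the go
signal (closed interval) are correct and rewarded; earlier releases are
*early errors*, later ones *late errors*. Error trials abort, and after a
1 s intertrial interval the same cue condition repeats until completed. The
task itself is trivially easy for a trained, motivated animal, so the error
rate E — the proportion of mistimed releases — is read as a behavioral index
of how much the animal values the offered outcome, not of its ability.

Two regularities structure the analysis:

1. **Incentive.** Error rate is inverse in cued reward size:

       E(R) = c / R + b

   with incentive scale c ≥ 0 (drops·probability) and baseline lapse rate
   b ∈ [0, 1]. Larger offers support stronger motivation, hence fewer
   errors.

2. **Satiation.** As the animal drinks through a session, the same offer is
   worth less. With Rcum the normalized cumulative reward (intake so far
   divided by the session total, so Rcum ∈ [0, 1)), reward value decays
   exponentially at rate λ ≥ 0:

       F(Rcum) = exp(−λ·Rcum),    V = R·F(Rcum)
       E(R, Rcum) = c / (R·F(Rcum)) + b

   λ = 0 recovers the pure incentive model exactly. Predictions are clipped
   to [0, 1]; clipped cells are counted and a fit where more than 20% of
   predictions clip emits a warning.

A note on functional form: written casually, the discounted model could
also be read as (c/R + b)·F(Rcum). That version makes error rates *fall*
as the animal satiates, which contradicts both the construct (satiation
lowers value, lowering value raises errors) and the observed pattern
(error curves rise with Rcum for every reward size). We therefore always
discount the *value* in the denominator, never the error rate itself.

## Satiation quartiles

Sessions are divided into quartiles of Rcum with half-open bins
[0.25(q−1), 0.25q), q = 1..4; an exact Rcum of 1 (possible only for a
hypothetical end-of-session datum) falls in quartile 4. Each quartile is
represented in fits and tables by its midpoint: 0.125, 0.375, 0.625, 0.875.
Rcum is credited *before* the current trial — satiation at decision time
reflects prior intake — and is normalized by the realized session total.
Binning is by reward volume, not trial count; the two differ when errors
interleave, and volume-based bins are what the quartile midpoints refer to.

## Fitting

Models are fitted to per-cell empirical error rates (one residual per
session × reward size, or per session × reward size × quartile cell) by
plain unweighted sum-of-squares. The optimizer is deterministic: a coarse
grid (log-spaced c with 0 prepended, 60 points on [0, 10]; linear b, 41
points on [0, 1]; linear λ, 41 points on [0, 20]) followed by bounded
trust-region least-squares refinement (`scipy.optimize.least_squares`,
ftol/xtol/gtol 1e-12) from the best five grid points. Ties among equal-SSE
optima break toward the smallest λ, then the smallest c. The pure
reward-size model requires ≥ 3 distinct reward sizes; the satiation model
≥ 2 reward sizes × ≥ 2 Rcum levels; anything less raises
`NonIdentifiableError` rather than fitting silently. The estimators follow
scikit-learn conventions (`fit`/`predict`, `get_params`, trailing-underscore
fitted attributes) so they compose with sklearn model-selection tooling;
`fit_reward_size_model` / `fit_satiation_model` are thin wrappers returning
a `FitResult` record. By default the pipeline fits the satiation model per
subject × treatment, and the reward-size model per treatment; any other
grouping can be passed explicitly.

## ANOVA

Hypothesis tests mirror an R `aov(response ~ f1 * f2 + Error(subject))`
call: subject is a between-unit error stratum, sessions provide the
within-subject replication, and fixed effects with all interactions are
tested against the within-subject residual. Computation is an OLS fit with
the subject factor entered first and sequential (type-I) sums of squares,
which coincide with the other SS types on balanced designs; unbalanced
input triggers a warning naming the convention. Satiation enters as a
4-level categorical quartile factor. No sphericity correction and no
multiple-testing adjustment are applied; both facts travel in the output
metadata.

The canonical designs are: error rate ~ treatment × reward; error rate ~
treatment × reward × quartile; mean correct reaction time ~ treatment ×
reward; early/late error ratio ~ treatment; total reward earned ~
treatment. The observation unit is configurable: session-level cells
(default for the two-way designs) or subject-level cell means. The
three-way design defaults to subject-level means — a full 2 subjects × 2
treatments × 4 rewards × 4 quartiles mean table leaves 31 residual degrees
of freedom, the aggregation consistent with how such designs are commonly
reported — because session-level and subject-level aggregation answer
slightly different questions and the choice should be explicit.

## The synthetic cohort generator

No public trial-level data accompany this task, so the generator is a
first-class, tested component that emulates the study conditions:

* 2 subjects × 2 treatments × 13 sessions per treatment (defaults),
  session cap 100 min, fixed 20 s mean trial duration (≈ 300 trials per
  session) plus the 1 s post-error intertrial interval. Only elapsed and
  cumulative quantities feed the analysis, so trial durations are not
  modelled stochastically.
* each new trial draws its cue uniformly from {1, 2, 4, 8}; an error trial
  repeats the same cue next;
* trial outcomes are Bernoulli with p = E(R, Rcum) from the satiation
  model. The realized session total is unknown mid-session, so the
  generator normalizes intake by an *expected* total fixed at session
  start (expected trial count × mean cue × P(correct at Rcum = 0.5)); the
  analysis side always re-normalizes by the realized total;
* reaction times are lognormal in log-ms with location 6.05 − 0.012·R
  (faster for larger offers) and scale 0.18, truncated into the accept
  window for correct trials and outside it for errors, split evenly
  between early and late (`early_error_share = 0.5`). This is the minimal
  latency structure that lets the reaction-time ANOVAs run end to end; no
  claim of kinematic realism is made;
* default treatment parameters are vehicle (c = 0.2, b = 0.05, λ = 1.0)
  and a disconnection-like agonist condition (c = 0.1, b = 0.05, λ = 0.3):
  under vehicle, error rates run from ≈ 28% (1 drop, first quartile) down
  to ≈ 8% (8 drops) and climb steeply late in the session — the magnitude
  and shape typical of this task — while the agonist condition shows the
  reduced incentive and flattened satiation sensitivity that functional
  disconnection produces;
* seeding: one top-level seed; per-session seeds derive from
  `SeedSequence([rng_seed, session_counter])`, so cohorts are bit
  reproducible and sessions independent.

What the generator does *not* emulate: visual discrimination difficulty
(accuracy is near ceiling when motivated), day-to-day parameter drift,
subject heterogeneity (both simulated subjects share the treatment
parameters), sequential dependencies beyond the error-repeat rule, and any
drug pharmacokinetics. Passing tests on simulated cohorts therefore
demonstrate that the analysis chain recovers what the generative model
puts in — not that real sessions satisfy the model.

## Calibration and recovery, with known caveats

* **Generative calibration.** At fixed Rcum, empirical error frequencies
  over 10,000 trials match the model probability within 3 binomial SE for
  every reward size and treatment (worst |z| ≈ 2.0 at seed 1).
* **Estimator-level recovery.** When cell rates are sampled binomially at
  the model's own predictions, the fitted ĉ and b̂ show no bias
  detectable at 3 SE over 60 replicates.
* **End-to-end recovery.** Running the full chain (simulate → realized-Rcum
  quartile cells at the midpoint covariates → fit) at the study-scale
  design leaves a small systematic bias, chiefly ĉ low by roughly 10%
  under vehicle. It stems from the two deliberate approximations above:
  the generator's expected-total normalization versus the analysis'
  realized-total normalization, and fitting at quartile midpoints while
  the model is convex in Rcum within each bin. Median absolute errors at
  study scale are ≈ 0.015 for c, ≈ 0.005 for b, and ≈ 0.07 (vehicle) /
  0.17 (agonist) for λ; the vehicle-above-agonist λ ordering is recovered
  in 100/100 replicate cohorts. These figures are recomputed, not quoted,
  by `scripts/acceptance.py`.
* **ANOVA calibration.** On null cohorts (identical treatment parameters)
  the treatment effect rejects at ≈ 3–5% at α = 0.05, within the binomial
  99% CI of the nominal rate over 200 replicates; permutation of treatment
  labels within subject yields uniform p-values (KS test). The treatment ×
  quartile interaction is detected in ≈ 100% of study-scale cohorts
  simulated with the default (vehicle vs disconnection-like) parameters.

Problem sizes used in the test suite and acceptance script — 100 recovery
cohorts, 200 null cohorts at 6 sessions × ≈ 100 trials, 40 power cohorts —
were chosen as the smallest designs at which the Monte-Carlo standard
errors are comfortably below the margins being asserted.

## Numerical details

* Error probabilities and fitted predictions clip to [0, 1]; the clipped
  fraction is reported per fit.
* Truncated-lognormal latencies are drawn via the Gaussian CDF/quantile
  pair (`scipy.special.ndtr`/`ndtri`) with tail-stable survival-function
  arithmetic, and nudged off the window boundaries by one ulp so the
  outcome labels and recorded latencies can never disagree.
* A constant response in the ANOVA (zero total variance) reports SS = 0
  and F = 0 for every effect instead of 0/0.
* The early/late error ratio is undefined (NaN, never raised) for sessions
  without late errors; ANOVA rows with missing responses are dropped with
  a count in the table notes.
* Sessions that deliver zero total reward have no Rcum normalization;
  `ZeroTotalRewardError` is raised explicitly.

## Known limitations

* The value model is fitted to binned rates, not by trial-level
  likelihood; standard errors for (c, b, λ) are not produced.
* No alternative discounting families (hyperbolic, temperature-scaled) and
  no mixed-effects alternative to the stratified ANOVA are provided.
* The quartile midpoint covariate slightly biases end-to-end parameter
  recovery (see above); fitting at trial-weighted within-bin mean Rcum
  would reduce it but break the fixed quartile-representative convention.
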