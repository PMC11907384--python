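# Methods

## Scope and model

`platsim` simulates one *domain* of an adaptive platform trial at a
time: k ≥ 2 arms, a binary guiding outcome, and Bayesian adaptive
analyses. The guiding outcome of arm `k` is Bernoulli with probability
`p_k`; a `direction` flag (`lower_better` for mortality-type outcomes)
orients every comparison, so data are never transformed. Each arm
carries an independent conjugate Beta posterior,
`p_k | data ~ Beta(α₀ + e_k, β₀ + n_k − e_k)`, with a Beta(1, 1) prior
by default (`prior_alpha`/`prior_beta` are design inputs; the platform
philosophy is a neutral prior that favours no arm).

The adaptive-analysis engine deliberately uses this unadjusted
beta-binomial model rather than the covariate-adjusted logistic model of
the final analysis: operating characteristics of multi-arm designs are
conventionally evaluated this way, the guiding outcome alone drives all
adaptations, and the adjusted estimator is exercised separately (see
*Final analysis* below). This gap between the simulation engine and the
final-analysis model is intentional.

All decision probabilities at one analysis — `P(arm k is best)`,
`P(better than control by > m)`, `P(|p_k − p_ctrl| < δ)`,
`P(max pairwise difference < δ)` — are estimated from a single shared
matrix of posterior draws (common random numbers), so the decisions
taken at one look cannot disagree with each other. The default is
10,000 draws per analysis (`n_draws`), configurable; batch-scale runs
in this repository use 2,500 (see *Problem sizes*).

## Trial mechanics

**Accrual** is a homogeneous Poisson process with rate
`accrual_rate` (patients/day, a scenario input) — the protocol family
this models does not fix an accrual model, and the rate sits in the
scenario so sensitivity analyses can vary it. **Outcome-data lag** =
guiding-outcome follow-up + a data collection/verification window
(default 15 days); a patient enters adaptive analyses only after the
lag elapses (inclusive boundary). Analyses fire the instant the
lag-complete count reaches the next trigger (`first_look_n`, then every
`look_interval_n`); calendar-alignment clauses (e.g. "first workday of
the month") affect logistics, not operating characteristics, and are
abstracted away. The schedule always ends with an analysis at `max_n`,
so inconclusiveness is declared only after the complete data have been
analysed. Patients randomised while outcomes are pending remain in the
trial; when a domain stops, every randomised patient is followed up and
included in the final tally.

**Adaptation rules.** Within one rule pass the precedence is
superiority → inferiority → equivalence → futility, so the strongest
conclusion wins; all decisions of a pass apply simultaneously, then the
analysis repeats on the reduced arm set until a pass changes nothing
(termination is guaranteed because each non-final pass removes an arm).
Status transitions are one-way. In common-control domains a superior
challenger is promoted to control (ties broken by the highest
probability of being overall best, then the lowest arm index) and the
old control is dropped; equivalence/futility are assessed only against
the original control unless `equivalence_vs_promoted_controls` is set.
If every arm of an all-vs-all domain simultaneously falls below the
inferiority threshold — possible only with inconsistent thresholds —
the arm with the highest `P(best)` is retained and the event is flagged
as degenerate in the decision. A domain whose active set shrinks to a
single arm stops for superiority of that arm. All-vs-all equivalence
uses the *joint per-draw* definition (`P(max pairwise difference < δ)`),
not the marginal per-pair one; the joint form is the stricter and more
interpretable reading of "all remaining arms within δ".

**Allocation.** Fixed profiles rescale over the surviving arms (equal
split, or the `√k : 1` control ratio recomputed with the current number
of non-control arms). Response-adaptive randomisation (RAR) uses
weights `P(best)^γ`: the softening exponent γ ∈ [0, 1] interpolates
between equal allocation (γ = 0) and raw probabilities (γ = 1); the
power form is the standard softening transform in this methodology.
Min/max limits are enforced after softening and normalisation by
clipping violators and renormalising the unclipped arms proportionally
until feasible (clipping before softening is a defensible alternative;
the difference only matters near the limits). With a fixed control
allocation, the control's probability is exact and the transform acts
on the remaining mass. Probabilities update only at analyses, never
between. Randomisation uses site-stratified permuted blocks before the
first adaptive analysis and simple randomisation afterwards (pending
blocks are discarded at the switch, in every allocation mode). Block
size is the smallest multiple of the ratio's denominator at or above
2 × (number of arms); for irrational target ratios the block
composition is randomised-remainder rounded, which keeps long-run
frequencies unbiased. The time-period index increments after every
analysis that changes anything (drop, promotion, or allocation update),
and each patient records the period in force at randomisation.

## Calibration and performance metrics

Type-1 error is defined as the probability of a **superiority** stop
under a null scenario (identical `p_k` everywhere); an equivalence stop
under the null is a correct conclusion, not an error.
`calibrate_superiority_threshold` bisects the superiority threshold
(default bracket 0.95–0.9995, tolerance 0.005), with the inferiority
threshold mirroring `1 − superiority` unless pinned; equivalence and
futility thresholds are design inputs held fixed. Every candidate is
evaluated on the *same* per-trial seed streams (common random numbers),
which makes the estimated error curve monotone in practice; the
returned threshold is the smallest examined value meeting the target on
that common batch, and should be validated on fresh seeds (the
acceptance script does exactly that). An unattainable target raises an
error rather than clamping.

Batch metrics: conclusiveness (any stop at or before `max_n`), stop-type
probabilities, per-arm selection probabilities, expected and SD of the
randomised sample size, mean number of analyses, mean proportion of
patients on the truly best arm(s) (all arms count under exact ties),
and the RMSE of the selected arm's final posterior median against its
true event probability. Trial `i` of a batch runs on seed stream
`(master_seed, i)`, so results are independent of worker count and any
single trial replays bit-exact in isolation; every result carries a
SHA-256 hash of the canonicalised design configuration.

## Final analysis (adjusted G-computation)

The final-analysis estimator is a Bayesian logistic regression of the
event on arm indicators plus site, sex, organ-support and comorbidity
flags, centred-and-scaled age, illness severity (0–42) and frailty
(1–9) with quadratic terms (squaring after scaling decorrelates the
linear and quadratic columns), and time-period indicators when more
than one period exists. Constant columns are absorbed by the intercept
and dropped; duplicate or otherwise collinear columns are an error.
Priors are zero-centred normals — SD 10 on every coefficient by default
(weakly informative on the log-odds scale); a *sceptical* analysis
passes a small `prior_scale_arm` (e.g. 0.35), shrinking arm contrasts
toward zero.

Two samplers are provided. The default **Laplace** approximation runs
Newton scoring to the penalised mode and draws from the Gaussian with
inverse observed-information covariance — at trial-sized n (thousands)
the logistic posterior under these priors is very nearly Gaussian, and
the fit is deterministic given the seed. The **emcee** ensemble sampler
(differential-evolution moves, initialised at the mode; 4,000 steps,
1,500 burn-in by default) provides a full-MCMC cross-check with
split-R-hat and effective-sample-size diagnostics computed over
walkers (thresholds 1.05 and 400); a fit outside the thresholds is
returned flagged with a warning, never silently.

Marginal effects are plain posterior G-computation: for each draw and
arm, predict every patient's risk with the arm set counterfactually,
average over patients, then contrast. (No extra robustification — e.g.
sandwich-type correction — is applied; with a correctly specified
working model the plug-in marginal contrast is consistent, and the term
"robust" is not given an operational definition in this setting.)
Summaries are posterior medians with 95% percentile intervals. Risk
differences are exactly antisymmetric under pair reversal; risk-ratio
medians invert exactly when the number of draws is odd.

## Synthetic data

The **trial-level** generator (the engine itself) draws arms, outcomes,
arrival times and site labels; it emulates a single closed domain with
complete outcome ascertainment. It does not model dropout or consent
withdrawal, site-level accrual heterogeneity, seasonal accrual,
staggered arm entry, co-enrolment across domains, or drift in the
event probability over calendar time — so passing operating
characteristics say nothing about time-trend bias, and the concurrent
time-period adjustment is exercised only through the period labels the
engine assigns.

The **patient-level** generator emulates an ICU baseline table: age
truncated-normal(65, 14) on [18, 95]; severity score integer 0–42
(truncated-normal(22, 7)); frailty integer 1–9; female sex 42%;
mechanical ventilation 60%; vasopressors 55%; RRT 10%; cancer 12%;
recent acute surgery 25%; eight sites of unequal size (largest 25%).
Events follow a logistic model with the configured coefficients; the
default intercept −1.7055 gives a reference-arm marginal risk of ≈0.25,
and an arm log-OR of −0.3059 gives a generator-true marginal risk
difference of ≈−0.05 (both solved once against the default covariate
mix). Generator-true marginal risks are computed by plug-in
potential-outcome averaging over the table's own covariate draws, so
recovery tests never rely on those frozen constants being exact. The
generator draws covariates independently (no correlation structure, no
missingness, no measurement error), so estimator checks demonstrate
correctness of the machinery, not robustness to real-data pathologies.

## Numerical choices

- Ties in `P(best)` within a draw (measure-zero for Beta posteriors but
  possible in floating point) split their mass equally among the tied
  arms — the expectation of uniform-random splitting — keeping the
  vector summing to 1 exactly and the computation deterministic.
- Thresholds compare strictly (`>` superiority, `<` inferiority), so a
  design with superiority 1.0 and inferiority 0.0 can never fire a
  rule: the null-design property used in tests. Inferiority 0.0 is
  accepted for exactly this reason.
- Allocation vectors are validated to sum to 1 within 1e−9; rescaling
  and clipping are exact to machine precision elsewhere.
- All randomness flows through `numpy` `SeedSequence` streams; derived
  streams are tuples `(seed, tag, …)` of small integers, never hashed
  floats. Replays are bit-exact on the same versions.
- The look at which a patient count triggers is computed from the
  arrival process directly (the c-th lag completion happens at
  `arrival_c + lag`), avoiding day-stepping loops.

## Problem sizes

Library defaults target production use (e.g. 10,000 posterior draws per
analysis; 100,000-simulation batches are a config choice). The
repository's own evaluation runs use desk-scale sizes chosen up front:
2,500 posterior draws per analysis, 2,000 common-seed simulations per
calibration step, 5,000 fresh-seed validation simulations, 1,000
simulations per conclusiveness scenario, and 100 replications at
n = 10,000 for marginal-effect recovery. Calibration and validation use
the same `n_draws`, so the threshold absorbs the Monte-Carlo noise of
the decision probabilities.

## Known limitations

- Binary guiding outcomes only; continuous and time-to-event guiding
  outcomes, frequentist group-sequential boundaries, multi-domain
  co-enrolment, and heterogeneous-treatment-effect analyses are out of
  scope.
- The simulator operates on complete data; multiple imputation of
  missing outcomes/covariates is orthogonal to the design machinery and
  not implemented.
- Site and period enter the final-analysis model as unpooled fixed
  effects; hierarchical pooling would be a natural extension.
- The equivalence definition in all-vs-all mode is joint-per-draw; a
  marginal per-pair variant would give systematically higher
  equivalence probabilities.
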