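# Methods

## Estimand and models

Let `A_t ∈ {0,1}` be a dichotomized sleep practice at assessment waves
`t = 1..5` (study labels 2, 3, 6, 8, 9), `V` the time-invariant baseline
covariates, `L_t` the time-varying covariates (depression band, self-rated
health, …), and `Y` a continuous substance-use frequency (0–7 scale) at the
final wave.  The estimand is the marginal dose–response slope `β` in the
marginal structural model

    E[Y(ā)] = β0 + β · Σ_t a_t + β_V V,

i.e. the change in expected counterfactual outcome per additional exposed
wave.  Operationally the package defines the target as the least-squares
slope of the exact `E[Y(ā)]` on `Σ a_t` over all 2^5 (or 2^2) fixed
regimes, which is what a weighted linear MSM estimates when the
counterfactual mean is linear in the dose (the generator is built so that
it is — see below).

Three estimators:

- **Model 1 (conventional)** — OLS of `Y` on the cumulative count,
  time-invariant covariates, *first-wave* time-varying covariates, and the
  other two practices' cumulative counts.  Biased when `L_t` is affected by
  earlier exposure.
- **Model 2 (stabilized-IPW MSM)** — WLS of `Y` on the cumulative count and
  time-invariant covariates only, weighted by stabilized IPTW × IPAW.
- **Model 3 (adjusted stabilized-IPW MSM)** — as Model 2 but the weight
  denominators additionally condition on the other two practices'
  current-wave indicators.

### Weights

Per wave (waves are unequally spaced, so no pooling across time), two
logistic regressions are fitted: the denominator
`P(A_t | A_{t−1}, cumA_{<t}, L_t, V)` and the numerator with the
time-varying block removed.  The exposure history is summarized by the
previous indicator plus the prior cumulative count rather than the full
2^{t−1} history — saturated history models are unstable at cohort-scale n.
The stabilization (numerator) covariates are baseline covariates plus
exposure history, the standard construction; they are retained in the
outcome MSM, which is what licenses stabilization.  Missing wave
indicators contribute nothing to the weight product and zero to the
cumulative count: persons are never dropped for interior-wave attrition,
which is instead handled by the attrition weights.

Attrition is modeled as per-wave *response* models, not monotone censoring
(the final wave is fully ascertained, so persons can return):
`P(observed_t | A_{t−1}, L_{t−1}, V)`, with covariates carried forward from
the last observed wave so the model conditions only on observable history.
The stabilized attrition factor multiplies `c_num/c_den` over the waves a
person was actually observed.  A wave with fewer than `min_attrition_events`
(default 5) dropouts is treated as non-informative — a response model on a
handful of events is noise — giving that wave a factor of exactly 1; the
same rule makes a fully retained cohort's IPAW identically 1.

Numerical guards: predicted probabilities are clipped to
`[ε, 1−ε], ε = 10⁻⁶` (clipping is logged, not fatal); apparent separation
(a degenerate response or |coefficient| > 30) raises a `SeparationError`
naming the wave and model; weight truncation at sample percentiles is
available but off by default.

All fits report heteroskedasticity-consistent (HC1) sandwich standard
errors, treating the weights as probability weights.  The sandwich ignores
the sampling variability of the estimated weights; in the recovery studies
this yields 95% CI coverage close to (slightly above) nominal.

### Missing items and entry rules

Item non-response in categorical covariates uses the indicator-variable
method: each variable gains a MISSING level and no row is dropped.  Cohort
entry excludes persons reporting any substance use at the first wave and
persons missing a final-wave outcome; both rules are idempotent and their
counts are logged.

## The synthetic cohort

The generator emulates a six-wave adolescent sleep survey with 2,690
entrants by default, including entry exclusions (7.66% baseline users,
29.96% missing final outcomes), interior attrition matching the motivating
cohort's pattern (≈0.3%, 0.9%, 21%, 18% at the four interior assessment
waves), 7% covariate item non-response, and per-wave exposure prevalences
near the published descriptive levels for all three practices.

Causal structure per person:

- `V ~ Bernoulli(0.5)` (emitted as gender, with five further inert
  time-invariant covariates at survey-like proportions);
- confounder: `L_t = 1{U < λ0 + λ·L_{t−1} + δ·A_{t−1}}` — a uniform-noise
  threshold, so the confounder's response is *linear in probability*;
- exposure: `A_t ~ Bernoulli(expit(α0_t + α_lag·A_{t−1} + α_conf·L_t +
  α_base·V))`;
- a latent post-exposure confounder state `M` follows the last wave (not
  emitted: the survey does not measure depression concurrently with the
  outcome);
- outcome: `Y = θ0 + θ1·ΣA_t + θ_conf·mean(L_2..L_5, M) + θ_base·V + ε`,
  `ε ~ N(0, σ²)`; an ordinal 0–7 clamp is available behind a flag
  (continuous is the default, keeping the estimand analytic).

Two design choices make the estimand clean.  First, the linear-probability
confounder response means `E[L_t(ā)]` follows an exact linear forward
recursion, so `E[Y(ā)]` is exactly linear in the regime; with the trailing
state `M` every exposure wave has one downstream mediated path, and for
`λ = 0` the causal slope is exactly `θ1 + θ_conf·δ/5` (with the default
`λ = 0.25` the per-wave effects differ by <1% and the g-formula slope is
the authority).  Second, because `E[Y(ā)]` is (essentially) linear in
`Σ a_t`, the uniform-regime least-squares slope, the pseudo-population
projection estimated by the stabilized MSM, and the closed form all agree,
so parameter-recovery comparisons are not contaminated by projection
mismatch.

Raw survey fields are emitted so that re-deriving each practice from them
reproduces the latent indicator exactly: integer-minute clock arithmetic
with a 6-minute guard around every cutoff (the weekly average equals the
drawn target exactly via a weekday/weekend split in multiples of 1/7 h),
bedtimes drawn in 22:00–24:29 so the bedtime-day convention is exercised on
both sides of midnight, and disturbance items forced positive exactly when
the latent indicator is 1.  The binary confounder maps onto the four
depression bands with the low/high bands split within each latent level, so
band-saturated logistic models are correctly specified.

The two nuisance practices follow their own logistic processes (driven by
`L_t` and their own lag) with, by default, no loading in the primary
exposure's propensity and no outcome effect — which is why Models 2 and 3
coincide asymptotically in the default scenarios.

What the generator does **not** emulate: the survey's multistage cluster
sampling, realistic marginal distributions of the inert covariates beyond
rough plausibility, measurement error in self-reports, or non-monotone
informative return patterns.  Passing tests therefore demonstrate estimator
correctness under the assumed causal structure, not robustness to
violations of it.

## The g-formula oracle

`counterfactual_mean` computes `E[Y(ā)]` exactly: by the linear forward
recursion for the continuous outcome, and by full enumeration over all
`2^(T+2)` latent branches (with the rounding/clamping handled through the
normal CDF) for the ordinal outcome.  `oracle_slope` regresses these means
on the dose over all regimes.  An independent brute-force enumeration and a
frozen hand-computed two-wave value guard the implementation in the tests.
`marginal_exposure_prevalence` provides exact per-wave exposure margins by
forward recursion over the joint confounder–exposure chain, used to check
the simulator against its own analytic marginals.

## Scenario presets and study sizes

Presets live in `msmcumexp/presets/` as YAML: `survey` (full realism),
`confounded` (clean recovery: feedback δ = 0.25 and confounding
α_conf = 1.3 active, no attrition/non-response, constructed so the
conventional model's bias exceeds 0.05 on the slope scale), `null`,
`attrition_informative` / `attrition_noninformative` (monotone interior
dropout at the 4th/5th assessment waves, driven by the previous wave's
state or by nothing), and `twowave` (hand-set coefficients, four regimes,
for exact oracle-equivalence checks).

The verification studies use: oracle equivalence at n = 200,000 on the
two-wave scenario; recovery and bias ordering over 200 replicates at
n = 2000; coverage over 500 replicates at n = 2000; attrition contrasts
over 100/60 replicates.  These sizes put Monte-Carlo error well below the
effects being measured while keeping the full suite's runtime modest.
Replicate seeds derive from a master seed as
`SeedSequence(master, spawn_key=(replicate,))`, so any replicate is
re-runnable in isolation and every artifact is bit-reproducible.

## Known limitations

- With interior-wave attrition, unobserved waves contribute zero to the
  cumulative exposure (the retained-person design).  This induces an
  exposure-measurement attenuation that attrition weighting does not
  target: under purely non-informative dropout both weighted arms carry the
  same attenuation, and under informative dropout IPAW removes the
  selection component only (the stress test shows a genuine but partial
  bias reduction).  Restricting to fully observed persons with pure IPCW
  would trade this for efficiency loss; the package follows the
  retained-person design.
- The IPAW covariate set is configurable rather than fixed: the appropriate
  conditioning set for dropout is study-specific.
- The MSM is linear in the dose; no ordinal/count-likelihood outcome models
  are provided.
- Sandwich SEs ignore weight estimation (mildly conservative in the
  scenarios tested, not guaranteed in general).
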