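# Methods

`socialstate` models the reproductive life-histories of male cooperative
breeders (banded-mongoose-like societies) as a discrete-time multistate
process over oestrus events, with companion regressions for paternity share,
oestrus weight change and lifetime reproductive success (LRS), and a
synthetic cohort generator that lets every stage be validated by parameter
recovery. This note records the models, their assumptions, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## The multistate model

Time is discretized by a group's oestrus events. At each event a male
occupies one of three live states — inactive **subordinate** (S), **sneaker**
(K), or mate-guarding **guard** (G) — and between consecutive events he
either dies or moves to a live state. The per-interval outcome law factorizes
into two separately fitted submodels:

* **Mortality** — Bernoulli with
  `logit P(dead) = alpha_s + beta_s * w + (age terms) + gamma * dt + u_event + u_group + u_male`,
  where `s` is the origin state, `w` the group-centred weight (the male's
  weight minus the mean weight of male group members at that event), `dt` the
  time to the group's next oestrus event in days, and the `u`s crossed
  zero-mean Gaussian random effects. State-specific intercepts *and*
  state-specific weight slopes encode condition-dependent mortality of
  reproductive activity (guards, not subordinates, pay for low weight).
* **Transitions** — conditional on survival, a multinomial logit over
  {S, K, G} with subordinate as the reference destination and
  origin-state-specific intercepts and slopes.

Both submodels come in two covariate variants, fitted separately because age
and the relative-rank/weight covariates are moderately correlated:
`age_rank` (within-group age rank, 1 = oldest) and `quadratic_age` (age and
age² in years). Group-centred weight is always included. The full 4×4
transition matrix (rows S, K, G, dead; dead absorbing) is composed only at
prediction time as `P(dead)` and `(1 − P(dead)) · softmax`, with random
effects at zero and non-focal covariates held at their sample means.

Sneaker states are carried in the likelihood so that transition
probabilities to guarding/subordinate roles account for them, but no
sneaker-specific outputs are produced; the sneaker destination is rare
(< 0.10 transition probability) across the covariate range.

**Covariate conventions.** Numerical covariates whose observed range is not
contained in [0, 1] are z-scored; the fitted scaler is persisted
(`scaler.json`) and reused at prediction time. Age rank ties (littermates)
break by lexicographic male id. Weight at an event is the most recent record
within a 30-day lookback before the event start. The group mean in
group-centred weight includes the focal male, so the covariate sums to zero
within an event.

**Inclusion rules and their likelihood consequences.** Males involved in
fewer than two oestrus events are excluded, and a death more than a year
after a male's last event is censored (his earlier intervals are kept). The
two-event rule has a structural consequence that is easy to miss: a male who
dies in his *first* interval ends up with a single event and is excluded
entirely, so no retained male can have a death in his first interval. Fitting
mortality on all rows therefore deflates mortality intercepts and distorts
the subordinate weight slope (young, light males dominate first intervals).
The mortality submodel consequently drops each male's first interval by
default (`ModelSpec.drop_first_interval`), which restores the correct
conditional likelihood under the inclusion rule. The transition submodel is
unaffected: it conditions on survival, and the destination carries no
selection given survival.

**Exposure covariate.** The mortality interval-length covariate is the time
from the origin event's end to the group's next oestrus event — for death
rows as well, since that is the exposure window in which the death occurred;
only a death after the group's last recorded event falls back to the death
date. Measuring death rows to the death date instead shortens them
systematically and biases the interval slope downward by most of a posterior
standard deviation at study scale.

## Companion fitness models

* **Paternity share**: binomial, `n` = total pups assigned to the oestrus
  event, `logit p` linear in group-centred weight (plus optional age-rank or
  quadratic-age terms), random effects for event, group and male.
* **Weight change**: Gaussian model of percentage weight change over an
  oestrus event with a subordinate mean and a guard contrast, residual SD,
  and the same crossed random effects. Age is deliberately omitted (it is
  collinear with state). The fit reports whether the guard interval excludes
  zero while the subordinate interval spans it.
* **LRS**: zero-inflated negative binomial. NB is parameterized by mean μ and
  dispersion φ (variance μ + μ²/φ); zero-inflation is intercept-only.
  Covariates are taken at the male's first event as a guard — either relative
  (age rank, group-centred weight) or absolute (age, weight) — with a group
  random intercept on the count part. Expected LRS is `(1 − π)·μ`.

## Inference

All models are fitted by an adaptive Metropolis-within-Gibbs sampler:

* fixed effects in blocks (one per origin state in the transition model),
  preconditioned with the Cholesky factor of `(X'X/n)^-1` and a scalar step
  adapted during burn-in toward 23% acceptance (40% for 1–2-dimensional
  blocks);
* random-effect levels as vectorized independent Metropolis updates (levels
  of one factor are conditionally independent given everything else), target
  acceptance 44%;
* random-effect SDs on the log scale against their half-Normal prior;
* two interweaving moves that break the well-known couplings of hierarchical
  models: a *translation* (shift intercepts against one random-effect field;
  likelihood-invariant) and a *rescaling* (scale one field and its SD
  together; run every third sweep since it costs a full likelihood pass).

Priors: fixed effects N(0, 2.5²) on the standardized scale; random-effect
SDs half-Normal(0, 1); log residual SD and log dispersion N(0, 1.5²). All
are overridable. Default chain settings mirror the original analyses
(3 chains; 50 000/5 000/100 iterations/burn-in/thinning for mortality,
20 000/2 000/100 for all other models); tests and the acceptance script use
shorter chains with thinning 1, which retains more draws per unit compute
and stabilizes the split-R̂ estimate. Convergence is monitored by
split-chain R̂ (< 1.1) per parameter. Initialization is at zero with
jittered retries if the likelihood is non-finite.

Sampler correctness is enforced by (i) exact quadrature on a one-parameter
Bernoulli model (posterior mean within 2 Monte-Carlo SEs), (ii) brute-force
likelihood oracles at 1e-10, and (iii) the recovery study below — not by
matching any reference sampler's output stream.

## The synthetic cohort generator

The generator is a full forward model of the study system, sized to the
study's random-effect structure: 20 groups followed for 5 years at ~4
oestrus events/year (gaps jittered around 91 days, minimum 30 days, events
lasting 7–10 days), ~8 adult males per group plus ~2.8 recruits per group
per year, giving ~375 events, ~320–400 males and ~3 000 transition
intervals. Males mature at 1 year, attend every event of their group while
alive, and are weighed a week before each event. Body weight follows a
saturating (von Bertalanffy-shaped) curve from 100 g at birth to a 1 456 g
adult plateau (rate 2.2/yr), declining 25 g/yr after a senescence onset at
8 years, with an additive individual frailty (SD 60 g) and measurement noise
(SD 25 g).

State transitions and mortality are drawn from exactly the laws the
inference modules fit, with raw-scale coefficients calibrated once so the
population-level behaviour matches the study system: stay-subordinate
fraction ≈ 0.65–0.7, subordinate-to-guard ≈ 0.2, guarding propensity peaking
at 6.5 years in the quadratic variant, per-interval mortality ≈ 7–8% with a
strongly negative guard weight slope (−0.0037/g) and a near-zero subordinate
slope, random-effect SDs 0.25–0.3. A `variant` switch selects whether age
rank or quadratic age is the generative age structure, because a recovery
study needs the fitted covariates to be the generative ones. Death dates are
assigned to the eve of the group's next event — in the field, deaths are
recognized as failures to reappear — which keeps the recorded exposure
window identical to the generative one. Paternity is allocated
multinomially across attending males with weights
`exp(0.004·w + 1.5·guard)` over litters of 1 + Poisson(2.8) pups assigned to
55% of events; weight changes are drawn per state (subordinate +0.21%,
guard −2.36%, SD 2.5%). Lifetime sired totals emerge from the paternity
process; an auxiliary direct ZINB generator (`simulate_lrs_table`) exists
for recovery tests of the LRS regression in isolation.

**What the generator does not emulate**: dispersal and eviction, female
identity and oestrus ordering, observation gaps (every living adult male is
observed at every event), seasonality, and litter failure dynamics beyond
the per-event assignment probability. Passing recovery tests therefore shows
the estimator is correct for data of this structure and size; it does not
show robustness to missed observations or model misspecification in real
field data.

## Validation design and tolerances

* Likelihood oracles: ≤ 20-row fixtures against explicit per-row
  recomputation, tolerance 1e-10.
* Transition-matrix structure: rows sum to 1 within 1e-12, dead row
  absorbing, monotone subordinate-to-guard response under a positive weight
  slope, and ZINB normalization/mean identities by direct summation.
* Parameter recovery: 20 replicate cohorts per generative variant at study
  scale, fitting the matching variant with 3 short chains. 95% credible
  intervals must cover each guard/subordinate-relevant fixed effect in ≥ 80%
  of replicates, and all assessed parameters must converge (R̂ < 1.1) in
  ≥ 80% of fits. Sneaker-specific parameters (origin- or destination-sneaker
  transition terms, sneaker mortality terms) are fitted but not assessed:
  they rest on ~140 of ~3 000 rows and, with at most one death per male, male
  frailty cannot be deconvolved from them at this scale — the same reason
  the sneaker analysis is reported nowhere in the package's outputs.
* The guarding peak: the quadratic-age switch point −b₁/(2b₂),
  back-transformed through the scaler, must have an interior maximum whose
  interval covers the generative 6.5 years.

Two caveats on recovery in a longitudinal design like this one. First, age
is partially confounded with event random effects (a cohort ages together
through its group's calendar), which inflates between-dataset variability of
the fitted age terms relative to the within-dataset posterior; with 20
groups this is modest but visible. Second, repeated outcomes select on male
frailty (males with high mortality effects leave the risk set), so marginal
age-mortality curves flatten relative to the conditional truth; the male
random effect corrects this only as far as it is identified. Both effects
are properties of the study design, not of the estimator.

## Numerical and degenerate-input behaviour

Logistic and multinomial likelihoods use `log_expit`/max-subtracted softmax
throughout; −∞ intercepts are valid and give probability 0 (used by the
immortal-cohort degenerate test). Zero-variance covariates fail
standardization with the covariate named. An all-zero LRS vector, a
single-state weight-change table, a single MCMC chain, or an empty design
table are rejected with explicit errors. Draws with exactly zero quadratic
curvature are skipped (and counted) in the switch-point posterior; if the
curvature is not predominantly negative the switch point is flagged as a
boundary case. Reports and CSV artifacts are byte-deterministic given their
inputs; the pipeline splits its global seed into per-stage sub-seeds by
hashing `"{seed}:{stage}"`.

## Design choices where the field leaves options open

* Reference destination = subordinate (the modal state).
* One shared random effect per (event, group, male) level added to both
  non-reference destination predictors, rather than destination-specific
  effects: it keeps generator and model coherent and identifiable at study
  scale.
* Covariate slopes are origin-state-specific; a slope-sharing switch is not
  provided (nothing downstream would consume it).
* Mortality time×covariate interactions are implemented behind a flag and
  off by default (they were not retained in the source analysis).
* Posterior-predictive curves condition non-focal covariates on their sample
  means and use equal-tailed 95% intervals.
* "Below average weight" means group-centred weight strictly below zero.
* Guard-vs-sneaker ties in daily behaviour records resolve to guard
  (guarding on any day is the defining behaviour).
* Litters link to the oestrus event whose end lies 44–74 days before the
  birth (nearest to 59 days wins ties).

## Known limitations

* The mortality submodel treats the time-to-next-event covariate as
  exogenous; in reality event timing could respond to group state.
* Random-effect posteriors for factors with few levels (group, n = 20) are
  prior-sensitive; intercept intervals inherit that width.
* The sampler is a random-walk scheme: adequate at ~30 parameters and ~3 000
  rows, but chain settings should be scaled up for larger designs.
* LRS counts include all pedigree-assigned offspring of reproductively
  active males, whether or not the siring event had behavioural coverage.
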