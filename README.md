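# socialstate

Hierarchical Bayesian models of male reproductive life-histories in
cooperatively breeding groups — who becomes reproductively active, when, at
what survival cost, and with what lifetime payoff.

In societies like banded mongoose groups, all breeding females enter oestrus
together and each is guarded by a single male. Whether a male guards, sneaks
matings, or stays inactive at a given oestrus event depends on his resource
holding potential — his weight and age relative to same-group rivals — and
reproductive activity carries energetic and survival costs that fall hardest
on low-condition males. `socialstate` implements the full analysis pipeline
for such data, together with a synthetic cohort generator so every stage can
be validated by parameter recovery without field data.

## The models

Time is discretized by oestrus events. Per interval between events, a male in
live state *s* ∈ {subordinate, sneaker, guard} either dies,

&nbsp;&nbsp;logit P(dead) = α_s + β_s·w + (age rank | age + age²) + γ·Δt +
u_event + u_group + u_male,

or, conditional on survival, transitions by a multinomial logit over the
three live states (subordinate = reference) with origin-specific intercepts
and slopes on group-centred weight *w* and the age covariates. The 4×4
transition matrix with its absorbing death state is composed at prediction
time. Companion models: binomial paternity share per event (trials = pups
assigned to the event), Gaussian percentage weight change (guard vs
subordinate), and zero-inflated negative binomial lifetime reproductive
success (LRS) against the covariates at first guarding. All models share an
adaptive Metropolis-within-Gibbs sampler with crossed random effects and
split-R̂ convergence checks. See `docs/methods.md` for the full
specification.

## Worked example

Simulate a study-scale cohort (20 groups, 5 years, ~4 oestrus events/year,
~3 000 transition intervals), build the design tables, and fit the
quadratic-age transition model:

```python
import socialstate as ss

cfg = ss.SimConfig(seed=1, true_params=ss.TrueParams(variant="quadratic_age"))
bundle = ss.simulate_population(cfg)
designs = ss.build_design_tables({
    "males": bundle.males, "events": bundle.events, "states": bundle.states,
    "weights": bundle.weights, "paternity": bundle.paternity,
    "weight_change": bundle.weight_change,
})
tr, scaler = designs["transitions"], designs["scaler"]
draws = ss.fit_transition(tr, "quadratic_age", scaler,
                          iterations=1600, burn_in=600, thin=1, seed=7)
peak = ss.quadratic_switch_point(draws, scaler)
print(len(tr), round(peak["mean"], 2), tuple(round(v, 2) for v in peak["ci"]))
```

```
2873 6.52 (6.23, 6.83)
```

2 873 transition intervals were retained after the inclusion filters, and the
fitted quadratic age effect puts the peak of guarding activity at 6.5 years
(95% credible interval 6.2–6.8) — males stay inactive well past sexual
maturity at 1 year, guard most around 6–7 years, and withdraw as condition
declines in old age. The cohort was generated with a true peak at 6.5 years,
so the interval covers the truth.

The same pipeline runs end-to-end from a shell:

```bash
socialstate -v run --config config.json   # simulate → preprocess → fit → predict → report
```

with a JSON config holding the seed, simulation settings and a list of model
fits; artifacts (dataset bundle, design tables, posterior draws, prediction
curves, raw-mortality table, markdown report, SHA-256 manifest) land in the
configured output directory.

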