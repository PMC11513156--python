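"""Synthetic cohort generator for male reproductive life-histories.

Simulates a banded-mongoose-like study population: social groups of roughly
10-30 adults that come into oestrus about four times a year, with a
male-biased adult sex ratio, growth towards an adult weight around 1.45 kg
followed by senescent decline after ~8 years, a guard / sneaker / subordinate
reproductive role structure, condition-dependent mortality between oestrus
events, and paternity skewed towards heavy, guarding males.

Every stochastic stage is driven by the exact generative laws the inference
modules fit (multinomial-logit state transitions, logit mortality with crossed
random effects, weight-skewed paternity allocation), so parameter recovery on
the simulator output is a meaningful end-to-end check of the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._calendar import DAYS_PER_YEAR, day_to_iso, years_between
from .codes import DEAD, GUARD, SNEAKER, SUBORDINATE
from .preprocessing import age_rank_vector


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Generative parameters
# ---------------------------------------------------------------------------

def _default_transition_age_rank() -> dict:
    # keys: (origin state, destination state) for non-reference destinations;
    # coefficients on raw scales (grams of group-centred weight, rank units)
    return {
        (SUBORDINATE, SNEAKER): {"intercept": -2.7, "weight": 0.0, "rank": 0.0},
        (SUBORDINATE, GUARD): {"intercept": 0.2, "weight": 0.005, "rank": -0.22},
        (SNEAKER, SNEAKER): {"intercept": -1.0, "weight": 0.0, "rank": 0.0},
        (SNEAKER, GUARD): {"intercept": -1.0, "weight": 0.003, "rank": 0.0},
        (GUARD, SNEAKER): {"intercept": -2.5, "weight": 0.0, "rank": 0.0},
        (GUARD, GUARD): {"intercept": 0.72, "weight": 0.004, "rank": -0.18},
    }


def _default_transition_quadratic_age() -> dict:
    # quadratic age structure: guarding propensity peaks at -age/(2*age2) = 6.5 y
    return {
        (SUBORDINATE, SNEAKER): {"intercept": -2.9, "weight": 0.0, "age": 0.10, "age2": -0.01},
        (SUBORDINATE, GUARD): {"intercept": -4.67, "weight": 0.005, "age": 1.56, "age2": -0.12},
        (SNEAKER, SNEAKER): {"intercept": -1.0, "weight": 0.0, "age": 0.0, "age2": 0.0},
        (SNEAKER, GUARD): {"intercept": -1.0, "weight": 0.003, "age": 0.0, "age2": 0.0},
        (GUARD, SNEAKER): {"intercept": -2.6, "weight": 0.0, "age": 0.0, "age2": 0.0},
        (GUARD, GUARD): {"intercept": -4.30, "weight": 0.005, "age": 1.56, "age2": -0.12},
    }


def _default_mortality_age_rank() -> dict:
    # state-specific intercepts/weight slopes (S, K, G); negative weight slope
    # for guards only => condition-dependent mortality of reproductive activity
    return {
        "alpha": [-2.73, -2.73, -2.67],
        "beta_weight": [0.0004, 0.0, -0.0037],
        "rank": -0.03,
        "interval": 0.005,
    }


def _default_mortality_quadratic_age() -> dict:
    return {
        "alpha": [-3.02, -3.02, -2.96],
        "beta_weight": [0.0004, 0.0, -0.0037],
        "age": 0.05,
        "age2": 0.0,
        "interval": 0.005,
    }


@dataclass
class TrueParams:
    """Generative parameter set mirrored by the inference modules.

    ``variant`` selects which age structure (within-group age rank, or
    quadratic absolute age) actually drives transitions and mortality; the
    matching model variant is the one whose recovery is well defined.
    """

    variant: str = "quadratic_age"
    transition_age_rank: dict = field(default_factory=_default_transition_age_rank)
    transition_quadratic_age: dict = field(default_factory=_default_transition_quadratic_age)
    trans_sd_event: float = 0.3
    trans_sd_group: float = 0.3
    trans_sd_male: float = 0.3
    mortality_age_rank: dict = field(default_factory=_default_mortality_age_rank)
    mortality_quadratic_age: dict = field(default_factory=_default_mortality_quadratic_age)
    mort_sd_event: float = 0.25
    mort_sd_group: float = 0.25
    mort_sd_male: float = 0.25
    # paternity allocation: softmax weights over attending males
    paternity: dict = field(default_factory=lambda: {"weight": 0.004, "guard": 1.5})
    # per-oestrus percentage weight change by state
    weight_change: dict = field(
        default_factory=lambda: {
            "mean": {SUBORDINATE: 0.21, SNEAKER: -1.0, GUARD: -2.36},
            "sd": 2.5,
        }
    )
    # lifetime reproductive success (zero-inflated negative binomial)
    lrs: dict = field(
        default_factory=lambda: {
            "zero_logit": -0.345,
            "log_mu0": 1.797,
            "weight": 0.003,
            "phi": 1.5,
            "group_sd": 0.2,
        }
    )

    def __post_init__(self) -> None:
        if self.variant not in ("age_rank", "quadratic_age"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        for sd in (
            self.trans_sd_event, self.trans_sd_group, self.trans_sd_male,
            self.mort_sd_event, self.mort_sd_group, self.mort_sd_male,
        ):
            if sd < 0:
                raise ConfigError("random-effect SDs must be non-negative")
        if self.weight_change["sd"] <= 0:
            raise ConfigError("weight-change SD must be positive")

    def transition_coeffs(self) -> dict:
        return (
            self.transition_age_rank
            if self.variant == "age_rank"
            else self.transition_quadratic_age
        )

    def mortality_coeffs(self) -> dict:
        return (
            self.mortality_age_rank
            if self.variant == "age_rank"
            else self.mortality_quadratic_age
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("transition_age_rank", "transition_quadratic_age"):
            d[key] = {f"{o}>{dst}": v for (o, dst), v in d[key].items()}
        d["weight_change"] = {
            "mean": {str(k): v for k, v in d["weight_change"]["mean"].items()},
            "sd": d["weight_change"]["sd"],
        }
        return d


@dataclass
class GrowthParams:
    """Saturating growth to an adult plateau, then linear senescent decline."""

    neonate_g: float = 100.0
    asymptote_g: float = 1456.0
    rate_per_year: float = 2.2
    senescence_onset_years: float = 8.0
    decline_g_per_year: float = 25.0
    frailty_sd_g: float = 60.0
    noise_sd_g: float = 25.0


@dataclass
class SimConfig:
    # defaults sized to the study system: ~20 groups followed for ~5 years at
    # ~4 oestrus events/year gives ~375 events, ~320 males and ~3000
    # transition intervals
    n_groups: int = 20
    years: float = 5.0
    mean_adult_males_per_group: float = 8.0
    events_per_year: float = 4.0
    seed: int = 0
    true_params: TrueParams = field(default_factory=TrueParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    adult_age_years: float = 1.0
    event_jitter_days: float = 15.0
    min_gap_days: int = 30
    event_duration_days: tuple = (7, 10)
    recruits_per_group_per_year: float = 2.8
    initial_age_range_years: tuple = (1.0, 9.0)
    litter_prob: float = 0.55
    mean_pups_per_litter: float = 3.8
    init_state_probs: tuple = (0.75, 0.05, 0.20)
    weigh_lead_days: int = 7

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if self.years <= 0:
            raise ConfigError("years must be positive")
        if self.events_per_year <= 0:
            raise ConfigError("events_per_year must be positive")
        if self.mean_adult_males_per_group <= 0:
            raise ConfigError("mean_adult_males_per_group must be positive")
        if abs(sum(self.init_state_probs) - 1.0) > 1e-9:
            raise ConfigError("init_state_probs must sum to 1")


# ---------------------------------------------------------------------------
# Growth and event scheduling
# ---------------------------------------------------------------------------

def simulate_growth_curve(age, params: GrowthParams | None = None):
    """Expected body weight (grams) at ``age`` (years).

    Monotone saturating rise from the neonate weight towards the adult
    asymptote, then a linear decline after the senescence onset.  Accepts
    scalars or arrays; negative ages raise ``ValueError``.
    """
    params = params or GrowthParams()
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("age must be non-negative")
    capped = np.minimum(age_arr, params.senescence_onset_years)
    w = params.neonate_g + (params.asymptote_g - params.neonate_g) * (
        1.0 - np.exp(-params.rate_per_year * capped)
    )
    w = w - params.decline_g_per_year * np.maximum(
        age_arr - params.senescence_onset_years, 0.0
    )
    return float(w) if np.isscalar(age) or age_arr.ndim == 0 else w


def schedule_events(
    lifespan_days: float,
    events_per_year: float,
    rng,
    jitter_days: float = 0.0,
    min_gap_days: int = 30,
    duration_days: tuple = (7, 10),
) -> list[tuple[int, int]]:
    """Schedule oestrus events over ``lifespan_days`` as (start, end) day pairs.

    Event starts sit on a regular grid with spacing ``DAYS_PER_YEAR /
    events_per_year`` plus Gaussian jitter, clipped so that consecutive events
    never overlap and keep at least ``min_gap_days`` between one event's end
    and the next one's start.
    """
    if lifespan_days <= 0:
        raise ConfigError("lifespan must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    base_gap = DAYS_PER_YEAR / events_per_year
    events: list[tuple[int, int]] = []
    k = 0
    prev_end = None
    while True:
        base = k * base_gap
        if base >= lifespan_days:
            break
        start = int(round(base + (rng.normal(0.0, jitter_days) if jitter_days > 0 else 0.0)))
        if prev_end is not None:
            start = max(start, prev_end + min_gap_days)
        if start >= lifespan_days:
            break
        dur = int(rng.integers(duration_days[0], duration_days[1] + 1))
        events.append((start, start + dur))
        prev_end = start + dur
        k += 1
    return events


# ---------------------------------------------------------------------------
# Linear predictors of the generative laws
# ---------------------------------------------------------------------------

def _age_term(coeffs: dict, rank, age):
    if "rank" in coeffs:
        return coeffs["rank"] * rank
    return coeffs["age"] * age + coeffs.get("age2", 0.0) * age ** 2


def transition_destination_probs(tp: TrueParams, origin: int, weight_c, rank, age, re: float = 0.0):
    """Generative P(subordinate, sneaker, guard) given survival, for one male."""
    coeffs = tp.transition_coeffs()
    eta = np.zeros(3)
    for dest in (SNEAKER, GUARD):
        c = coeffs[(origin, dest)]
        eta[dest] = c["intercept"] + c["weight"] * weight_c + _age_term(c, rank, age) + re
    eta -= eta.max()
    p = np.exp(eta)
    return p / p.sum()


def mortality_prob(tp: TrueParams, state: int, weight_c, rank, age, gap_days, re: float = 0.0):
    """Generative probability of dying before the next oestrus event."""
    m = tp.mortality_coeffs()
    eta = (
        m["alpha"][state]
        + m["beta_weight"][state] * weight_c
        + _age_term(m, rank, age)
        + m["interval"] * gap_days
        + re
    )
    return float(expit(eta))


def outcome_probs(tp: TrueParams, state: int, weight_c, rank, age, gap_days,
                  re_mort: float = 0.0, re_trans: float = 0.0) -> np.ndarray:
    """Full per-interval outcome law (S, K, G, dead); sums to 1."""
    pd_ = mortality_prob(tp, state, weight_c, rank, age, gap_days, re_mort)
    live = transition_destination_probs(tp, state, weight_c, rank, age, re_trans)
    return np.append((1.0 - pd_) * live, pd_)


def draw_interval_outcome(tp: TrueParams, state: int, weight_c, rank, age, gap_days,
                          rng, re_mort: float = 0.0, re_trans: float = 0.0) -> int:
    """Draw one interval outcome (next state, or DEAD) from the generative law.

    This is the exact sampling path the population simulator uses: death is
    decided first, then the live destination conditional on survival.
    """
    p_die = mortality_prob(tp, state, weight_c, rank, age, gap_days, re_mort)
    if rng.uniform() < p_die:
        return DEAD
    probs = transition_destination_probs(tp, state, weight_c, rank, age, re_trans)
    return int(rng.choice(3, p=probs))


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Dataset bundle produced by :func:`simulate_population`."""

    males: pd.DataFrame
    events: pd.DataFrame
    states: pd.DataFrame
    weights: pd.DataFrame
    paternity: pd.DataFrame
    weight_change: pd.DataFrame
    true_params: TrueParams
    config: SimConfig

    _TABLES = ("males", "events", "states", "weights", "paternity", "weight_change")

    def write(self, outdir) -> list[pathlib.Path]:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self._TABLES:
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(path)
        path = outdir / "true_params.json"
        path.write_text(json.dumps(self.true_params.to_dict(), indent=1, sort_keys=True))
        written.append(path)
        return written


class _Male:
    __slots__ = ("mid", "birth", "frailty", "u_t", "u_m", "state", "death_day")

    def __init__(self, mid, birth, frailty, u_t, u_m):
        self.mid = mid
        self.birth = birth
        self.frailty = frailty
        self.u_t = u_t
        self.u_m = u_m
        self.state = None      # state to occupy at the next attended event
        self.death_day = None


def simulate_population(config: SimConfig) -> SimBundle:
    """Simulate the full dataset bundle from a known parameterization.

    Death is absorbing; every exported male attended at least one oestrus
    event; per-event paternity totals equal the sum of per-male sired counts.
    Identical config (including seed) gives byte-identical CSV output.
    """
    rng = np.random.default_rng(config.seed)
    tp = config.true_params
    gp = config.growth
    sim_days = int(round(config.years * DAYS_PER_YEAR))

    males_rows, events_rows, states_rows = [], [], []
    weights_rows, pat_rows, wc_rows = [], [], []
    n_males = 0
    n_events = 0

    for g in range(config.n_groups):
        gid = f"G{g:02d}"
        ug_t = rng.normal(0.0, tp.trans_sd_group)
        ug_m = rng.normal(0.0, tp.mort_sd_group)
        events = schedule_events(
            sim_days, config.events_per_year, rng,
            jitter_days=config.event_jitter_days,
            min_gap_days=config.min_gap_days,
            duration_days=config.event_duration_days,
        )

        roster: list[_Male] = []

        def _new_male(birth_day: int) -> _Male:
            nonlocal n_males
            m = _Male(
                f"M{n_males:04d}",
                birth_day,
                rng.normal(0.0, gp.frailty_sd_g),
                rng.normal(0.0, tp.trans_sd_male),
                rng.normal(0.0, tp.mort_sd_male),
            )
            n_males += 1
            return m

        n0 = max(1, int(rng.poisson(config.mean_adult_males_per_group)))
        for _ in range(n0):
            age0 = rng.uniform(*config.initial_age_range_years)
            roster.append(_new_male(-int(round(age0 * DAYS_PER_YEAR))))
        n_rec = int(rng.poisson(config.recruits_per_group_per_year * config.years))
        latest_birth = max(int(sim_days - DAYS_PER_YEAR), -729)
        for _ in range(n_rec):
            roster.append(_new_male(int(rng.integers(-730, latest_birth + 1))))

        for i, (start, end) in enumerate(events):
            eid = f"E{n_events:04d}"
            n_events += 1
            events_rows.append(
                {"event_id": eid, "group_id": gid,
                 "start_date": day_to_iso(start), "end_date": day_to_iso(end)}
            )
            ue_t = rng.normal(0.0, tp.trans_sd_event)
            ue_m = rng.normal(0.0, tp.mort_sd_event)

            attendees = [
                m for m in roster
                if m.death_day is None
                and years_between(m.birth, start) >= config.adult_age_years
            ]
            if not attendees:
                continue

            weigh_day = start - config.weigh_lead_days
            ages = np.array([years_between(m.birth, start) for m in attendees])
            w_meas = np.array([
                simulate_growth_curve(max(years_between(m.birth, weigh_day), 0.0), gp)
                + m.frailty + rng.normal(0.0, gp.noise_sd_g)
                for m in attendees
            ])
            w_meas = np.round(np.maximum(w_meas, 50.0), 1)
            for m, w in zip(attendees, w_meas):
                weights_rows.append(
                    {"male_id": m.mid, "date": day_to_iso(weigh_day), "weight_g": w}
                )

            ids = [m.mid for m in attendees]
            ranks = age_rank_vector(ages, ids)
            w_centred = w_meas - w_meas.mean()

            # realize states for this event
            states = []
            for m in attendees:
                if m.state is None:
                    if i == 0:
                        m.state = int(rng.choice(3, p=config.init_state_probs))
                    else:
                        m.state = SUBORDINATE
                states.append(m.state)
                states_rows.append({"male_id": m.mid, "event_id": eid, "state": m.state})

            # per-oestrus percentage weight change
            for m, s in zip(attendees, states):
                wc_rows.append({
                    "male_id": m.mid, "event_id": eid, "state": s,
                    "pct_change": round(rng.normal(tp.weight_change["mean"][s],
                                                   tp.weight_change["sd"]), 3),
                })

            # paternity of the litter conceived at this event (if assigned)
            if rng.uniform() < config.litter_prob:
                total = 1 + int(rng.poisson(config.mean_pups_per_litter - 1.0))
                alloc = np.exp(
                    tp.paternity["weight"] * w_centred
                    + tp.paternity["guard"] * (np.array(states) == GUARD)
                )
                sired = rng.multinomial(total, alloc / alloc.sum())
                for m, k in zip(attendees, sired):
                    pat_rows.append({
                        "male_id": m.mid, "event_id": eid, "group_id": gid,
                        "sired": int(k), "event_total": total,
                    })

            # transition to the group's next event
            if i + 1 >= len(events):
                continue
            next_start = events[i + 1][0]
            gap = next_start - end
            for m, s, wc, rk, age in zip(attendees, states, w_centred, ranks, ages):
                outcome = draw_interval_outcome(
                    tp, s, wc, rk, age, gap, rng,
                    re_mort=ug_m + ue_m + m.u_m, re_trans=ug_t + ue_t + m.u_t,
                )
                if outcome == DEAD:
                    m.death_day = next_start - 1
                m.state = outcome

        attended = {r["male_id"] for r in states_rows}
        for m in roster:
            if m.mid not in attended:
                continue
            males_rows.append({
                "male_id": m.mid, "group_id": gid,
                "birth_date": day_to_iso(m.birth),
                "death_date": day_to_iso(m.death_day) if m.death_day is not None else "",
            })

    males = pd.DataFrame(males_rows).sort_values("male_id", ignore_index=True)
    bundle = SimBundle(
        males=males,
        events=pd.DataFrame(events_rows),
        states=pd.DataFrame(states_rows),
        weights=pd.DataFrame(weights_rows),
        paternity=pd.DataFrame(pat_rows),
        weight_change=pd.DataFrame(wc_rows),
        true_params=tp,
        config=config,
    )
    return bundle


def simulate_lrs_table(
    lrs_params: dict,
    n_males: int = 229,
    n_groups: int = 15,
    weight_sd_g: float = 150.0,
    rng=None,
) -> pd.DataFrame:
    """Draw lifetime-reproductive-success counts straight from the ZINB law.

    Used for recovery tests of the LRS regression in isolation from the rest
    of the pipeline: the covariate is group-centred weight at first guarding,
    the count mean is log-linear in it, and a group-level random intercept
    enters the count part.
    """
    rng = np.random.default_rng(rng)
    p = lrs_params
    group = rng.integers(0, n_groups, n_males)
    u_g = rng.normal(0.0, p.get("group_sd", 0.0), n_groups)
    w = rng.normal(0.0, weight_sd_g, n_males)
    mu = np.exp(p["log_mu0"] + p["weight"] * w + u_g[group])
    phi = p["phi"]
    extra_zero = rng.uniform(size=n_males) < expit(p["zero_logit"])
    counts = rng.negative_binomial(phi, phi / (phi + mu))
    lrs = np.where(extra_zero, 0, counts)
    return pd.DataFrame({
        "male_id": [f"M{i:04d}" for i in range(n_males)],
        "group_id": [f"G{int(g):02d}" for g in group],
        "group_centred_weight": w,
        "lrs": lrs.astype(int),
    })
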