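"""Turn raw observation tables into model-ready design tables.

Covers per-event behavioural state summaries, the relative resource-holding
covariates (age rank, group-centred weight), covariate standardization with a
persistable scaler, construction of per-interval transition observations with
the study's inclusion filters, litter-to-oestrus-event linking via the
gestation window, and a collinearity report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._calendar import iso_to_day, years_between
from .codes import DEAD, GUARD, SNEAKER, SUBORDINATE

log = logging.getLogger(__name__)

#: days after the last attended event beyond which a death is censored out
DEATH_WINDOW_DAYS = 365
#: default lookback (days) when matching a weight record to an event
WEIGHT_LOOKBACK_DAYS = 30
#: gestation window linking a litter birth back to an oestrus event:
#: the event must have ended 59 +/- 15 days before the birth
GESTATION_GAP_DAYS = 59
GESTATION_WINDOW_DAYS = (44, 74)


# ---------------------------------------------------------------------------
# Elementary covariate operations
# ---------------------------------------------------------------------------

def summarize_event_state(daily_records) -> int:
    """Collapse daily behaviour records over one oestrus event into one state.

    A male that guarded on any day is a guard, unless he used sneaky tactics
    on more days than he guarded, in which case he is a sneaker.  A male with
    no reproductive activity on any day is an inactive subordinate.  When
    guard-days equal sneak-days the male counts as a guard (guarding on any
    day is the defining behaviour).
    """
    records = list(daily_records)
    if not records:
        raise ValueError("daily record list must not be empty")
    allowed = {"guard", "sneak", "none"}
    bad = set(records) - allowed
    if bad:
        raise ValueError(f"unknown behaviour records: {sorted(bad)}")
    n_guard = records.count("guard")
    n_sneak = records.count("sneak")
    if n_sneak > n_guard and n_sneak >= 1:
        return SNEAKER
    if n_guard >= 1:
        return GUARD
    return SUBORDINATE


def compute_group_centred_weight(male_weight: float, group_male_weights) -> float:
    """Focal weight minus the mean weight of adult male group members.

    The focal male is included in the mean, so group-centred weights sum to
    zero within an event when every member is weighed.
    """
    weights = np.asarray(list(group_male_weights), dtype=float)
    if weights.size == 0:
        raise ValueError("group weight list must not be empty")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(male_weight - weights.mean())


def age_rank_vector(ages, ids) -> np.ndarray:
    """Within-group age ranks, 1 = oldest; ties broken by lexicographic id."""
    ages = np.asarray(ages, dtype=float)
    order = sorted(range(len(ages)), key=lambda i: (-ages[i], str(ids[i])))
    ranks = np.empty(len(ages), dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return ranks


def compute_age_rank(ages_of_group_males, focal_index: int, ids=None) -> int:
    """Age rank of one male among his same-sex group members (1 = oldest)."""
    ages = list(ages_of_group_males)
    if not ages:
        raise ValueError("age list must not be empty")
    if ids is None:
        ids = [str(i) for i in range(len(ages))]
    return int(age_rank_vector(ages, ids)[focal_index])


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class CovariateScaler:
    """Per-covariate centre/scale used for standardization.

    Covariates whose observed range is not contained in [0, 1] are z-scored;
    those already inside [0, 1] pass through unchanged (centre 0, scale 1).
    The fitted scaler is persisted so prediction reuses the training-time
    transform exactly.
    """

    params: dict  # name -> {"centre": float, "scale": float, "standardized": bool}

    @classmethod
    def fit(cls, df: pd.DataFrame, columns) -> "CovariateScaler":
        params = {}
        for col in columns:
            vals = np.asarray(df[col], dtype=float)
            if np.unique(vals).size < 2:
                raise ValueError(f"covariate {col!r} has zero variance")
            if vals.min() >= 0.0 and vals.max() <= 1.0:
                params[col] = {"centre": 0.0, "scale": 1.0, "standardized": False}
            else:
                params[col] = {
                    "centre": float(vals.mean()),
                    "scale": float(vals.std(ddof=0)),
                    "standardized": True,
                }
        return cls(params)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, p in self.params.items():
            if col in out:
                out[col] = (np.asarray(out[col], dtype=float) - p["centre"]) / p["scale"]
        return out

    def transform_values(self, name: str, values):
        p = self.params[name]
        return (np.asarray(values, dtype=float) - p["centre"]) / p["scale"]

    def inverse_values(self, name: str, values):
        p = self.params[name]
        return np.asarray(values, dtype=float) * p["scale"] + p["centre"]

    def to_json(self, path=None) -> str:
        text = json.dumps(self.params, indent=1, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CovariateScaler":
        path = pathlib.Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls(json.loads(text))


def standardize(values, scaler: CovariateScaler | None = None, name: str = "x"):
    """Standardize one covariate vector under the range rule.

    Returns ``(transformed values, scaler)``.  With a pre-fitted scaler the
    stored centre/scale are reused; otherwise a new scaler is fitted.
    """
    df = pd.DataFrame({name: np.asarray(values, dtype=float)})
    if scaler is None:
        scaler = CovariateScaler.fit(df, [name])
    return scaler.transform_values(name, values), scaler


# ---------------------------------------------------------------------------
# Bundle IO and event-level covariates
# ---------------------------------------------------------------------------

def load_bundle(directory) -> dict:
    """Read the canonical dataset bundle CSVs into DataFrames."""
    directory = pathlib.Path(directory)
    out = {}
    for name in ("males", "events", "states", "weights", "paternity", "weight_change"):
        path = directory / f"{name}.csv"
        if path.exists():
            out[name] = pd.read_csv(path, keep_default_na=False)
    return out


def _event_index(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.copy()
    ev["start_day"] = ev["start_date"].map(iso_to_day)
    ev["end_day"] = ev["end_date"].map(iso_to_day)
    return ev.set_index("event_id")


def _weight_lookup(weights: pd.DataFrame):
    """Per-male sorted (day, weight) arrays for lookback matching."""
    table = {}
    for mid, sub in weights.groupby("male_id"):
        days = sub["date"].map(iso_to_day).to_numpy()
        order = np.argsort(days, kind="stable")
        table[mid] = (days[order], sub["weight_g"].to_numpy(dtype=float)[order])
    return table


def event_covariates(
    states: pd.DataFrame,
    events: pd.DataFrame,
    males: pd.DataFrame,
    weights: pd.DataFrame,
    lookback_days: int = WEIGHT_LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Per (male, event) covariates: age, age rank, group-centred weight.

    Weight at an event is the most recent record within ``lookback_days``
    before the event start.  Males without a matching weight record get NaN
    group-centred weight and are excluded from the group mean.
    """
    ev = _event_index(events)
    birth = males.set_index("male_id")["birth_date"].map(iso_to_day)
    wtab = _weight_lookup(weights)

    rows = []
    for eid, sub in states.groupby("event_id", sort=False):
        start = int(ev.loc[eid, "start_day"])
        ids = sub["male_id"].tolist()
        ages = np.array([years_between(birth[m], start) for m in ids])
        ranks = age_rank_vector(ages, ids)
        w = np.full(len(ids), np.nan)
        for j, m in enumerate(ids):
            if m not in wtab:
                continue
            days, vals = wtab[m]
            k = np.searchsorted(days, start, side="right") - 1
            if k >= 0 and start - days[k] <= lookback_days:
                w[j] = vals[k]
        mean_w = np.nanmean(w) if np.isfinite(w).any() else np.nan
        for j, m in enumerate(ids):
            rows.append({
                "male_id": m, "event_id": eid,
                "group_id": ev.loc[eid, "group_id"],
                "state": int(sub["state"].iloc[j]),
                "age_years": ages[j],
                "age_rank": int(ranks[j]),
                "weight_g": w[j],
                "group_centred_weight": w[j] - mean_w,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transition table
# ---------------------------------------------------------------------------

def build_transition_table(
    states: pd.DataFrame,
    events: pd.DataFrame,
    males: pd.DataFrame,
    weights: pd.DataFrame,
    lookback_days: int = WEIGHT_LOOKBACK_DAYS,
    death_window_days: int = DEATH_WINDOW_DAYS,
) -> pd.DataFrame:
    """One observation per (event t -> event t+1) interval per male.

    Males involved in fewer than two oestrus events contribute nothing.  A
    death within ``death_window_days`` of the last attended event's end adds a
    terminal interval with outcome ``dead``; later deaths are censored out
    (the male's earlier intervals are kept).  Interval length is the time to
    the next oestrus event (the mortality model's exposure covariate): for
    death rows it runs to the group's next scheduled event, falling back to
    the death date when the group held no further event.  A state recorded
    after a male's death raises a data-integrity error.
    """
    ev = _event_index(events)
    minfo = males.set_index("male_id")
    cov = event_covariates(states, events, males, weights, lookback_days)
    cov = cov.set_index(["male_id", "event_id"])
    # next scheduled event of each group after a given event: the exposure
    # window for the mortality covariate ("time to next oestrus event")
    next_start = {}
    for gid, sub in ev.reset_index().groupby("group_id"):
        sub = sub.sort_values("start_day")
        for cur, nxt in zip(sub["event_id"], sub["start_day"].shift(-1)):
            next_start[cur] = None if pd.isna(nxt) else int(nxt)

    rows = []
    n_late_death = 0
    for mid, sub in states.groupby("male_id", sort=False):
        eids = sub["event_id"].tolist()
        starts = np.array([ev.loc[e, "start_day"] for e in eids])
        order = np.argsort(starts, kind="stable")
        eids = [eids[i] for i in order]
        state_by_event = dict(zip(sub["event_id"], sub["state"]))

        death_raw = minfo.loc[mid, "death_date"] if "death_date" in minfo else ""
        death_day = iso_to_day(death_raw) if str(death_raw) not in ("", "nan") else None
        if death_day is not None and any(
            ev.loc[e, "start_day"] > death_day for e in eids
        ):
            raise ValueError(f"state recorded after death for male {mid}")

        if len(eids) < 2:
            continue

        def _row(e_from, e_to, outcome, interval):
            c = cov.loc[(mid, e_from)]
            rows.append({
                "male_id": mid,
                "group_id": ev.loc[e_from, "group_id"],
                "event_from": e_from,
                "event_to": e_to,
                "origin_state": int(state_by_event[e_from]),
                "outcome": int(outcome),
                "age_years": float(c["age_years"]),
                "age_rank": int(c["age_rank"]),
                "group_centred_weight": float(c["group_centred_weight"]),
                "interval_days": int(interval),
            })

        for e_from, e_to in zip(eids[:-1], eids[1:]):
            _row(e_from, e_to, state_by_event[e_to],
                 ev.loc[e_to, "start_day"] - ev.loc[e_from, "end_day"])
        if death_day is not None:
            last = eids[-1]
            gap = death_day - ev.loc[last, "end_day"]
            if gap <= death_window_days:
                # exposure runs to the group's next scheduled event when one
                # exists (the model's "time to next oestrus event"); only a
                # death after the group's last event falls back to the death
                # date itself
                nxt = next_start.get(last)
                if nxt is not None and nxt > death_day:
                    interval = nxt - ev.loc[last, "end_day"]
                else:
                    interval = max(gap, 0)
                _row(last, "", DEAD, interval)
            else:
                n_late_death += 1

    out = pd.DataFrame(rows)
    if len(out):
        # 0-based interval counter per male (rows are chronological per male);
        # under the two-event inclusion rule a death can never fall in a
        # male's first interval, so downstream mortality fits can condition
        # on this structural selection
        out["interval_index"] = out.groupby("male_id").cumcount()
        n_missing = int(out["group_centred_weight"].isna().sum())
        if n_missing:
            log.warning("dropping %d transition rows without a matched weight", n_missing)
            out = out.dropna(subset=["group_centred_weight"]).reset_index(drop=True)
    out.attrs["n_late_death_censored"] = n_late_death
    return out


# ---------------------------------------------------------------------------
# Litter linking and collinearity
# ---------------------------------------------------------------------------

def link_litters_to_events(
    litters: pd.DataFrame,
    events: pd.DataFrame,
    window_days: tuple = GESTATION_WINDOW_DAYS,
    target_gap_days: int = GESTATION_GAP_DAYS,
) -> pd.DataFrame:
    """Link each litter to the oestrus event of its conception.

    A litter links to the event of its group whose end date fell
    ``window_days`` (default 44-74) before the litter's birth date; with two
    candidates the one nearest the modal gestation gap (59 days) wins.
    Unlinked litters get a missing event id and are logged.
    """
    ev = events.copy()
    ev["end_day"] = ev["end_date"].map(iso_to_day)
    lo, hi = window_days
    rows = []
    for _, lit in litters.iterrows():
        birth = iso_to_day(lit["birth_date"])
        cands = ev[ev["group_id"] == lit["group_id"]].copy()
        cands["gap"] = birth - cands["end_day"]
        cands = cands[(cands["gap"] >= lo) & (cands["gap"] <= hi)]
        if len(cands) == 0:
            log.info("litter %s unlinked (no event in gestation window)", lit["litter_id"])
            linked, gap = "", np.nan
        else:
            best = cands.iloc[(cands["gap"] - target_gap_days).abs().argsort(kind="stable")].iloc[0]
            linked, gap = best["event_id"], int(best["gap"])
        rows.append({"litter_id": lit["litter_id"], "event_id": linked, "gap_days": gap})
    return pd.DataFrame(rows)


def diagnose_collinearity(
    design: pd.DataFrame, columns=None, threshold: float = 0.7
) -> pd.DataFrame:
    """Pairwise Pearson correlations among covariates, flagged above a threshold."""
    if len(design) < 3:
        raise ValueError("need at least 3 rows for a correlation report")
    if columns is None:
        columns = [c for c in design.columns if np.issubdtype(design[c].dtype, np.number)]
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            x = np.asarray(design[a], dtype=float)
            y = np.asarray(design[b], dtype=float)
            if x.std() == 0 or y.std() == 0:
                r = np.nan
                note = "constant column; correlation undefined"
            else:
                r = float(np.corrcoef(x, y)[0, 1])
                note = ""
            rows.append({
                "var1": a, "var2": b, "r": r,
                "flagged": bool(np.isfinite(r) and abs(r) >= threshold),
                "note": note,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full design-table construction
# ---------------------------------------------------------------------------

def build_design_tables(bundle: dict, outdir=None) -> dict:
    """Build all model-ready tables from a dataset bundle.

    Returns a dict with ``transitions``, ``paternity_design``,
    ``weightchange_design``, ``lrs_design`` and the fitted ``scaler``;
    optionally writes them (plus ``scaler.json``) to ``outdir``.
    """
    states, events = bundle["states"], bundle["events"]
    males, weights = bundle["males"], bundle["weights"]

    transitions = build_transition_table(states, events, males, weights)
    transitions["age_sq"] = transitions["age_years"] ** 2
    scaler = CovariateScaler.fit(
        transitions,
        ["age_years", "age_sq", "age_rank", "group_centred_weight", "interval_days"],
    )

    cov = event_covariates(states, events, males, weights)

    paternity_design = bundle["paternity"].merge(
        cov[["male_id", "event_id", "age_years", "age_rank", "group_centred_weight"]],
        on=["male_id", "event_id"], how="left",
    ).dropna(subset=["group_centred_weight"]).reset_index(drop=True)
    paternity_design["age_sq"] = paternity_design["age_years"] ** 2

    weightchange_design = bundle["weight_change"].merge(
        cov[["male_id", "event_id", "group_id"]], on=["male_id", "event_id"], how="left"
    )
    weightchange_design = weightchange_design[
        weightchange_design["state"].isin([SUBORDINATE, GUARD])
    ].reset_index(drop=True)

    lrs_design = _build_lrs_design(cov, bundle["paternity"])

    out = {
        "transitions": transitions,
        "paternity_design": paternity_design,
        "weightchange_design": weightchange_design,
        "lrs_design": lrs_design,
        "scaler": scaler,
    }
    if outdir is not None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("transitions", "paternity_design", "weightchange_design", "lrs_design"):
            out[name].to_csv(outdir / f"{name}.csv", index=False)
        scaler.to_json(outdir / "scaler.json")
    return out


def _build_lrs_design(cov: pd.DataFrame, paternity: pd.DataFrame) -> pd.DataFrame:
    """Lifetime reproductive success per reproductively active male.

    First reproductive activity is the first event at which a male's
    summarized state is guard; covariates are taken at that event.  LRS is
    the male's total pedigree-assigned offspring over all events.
    """
    lrs_total = paternity.groupby("male_id")["sired"].sum()
    guards = cov[cov["state"] == GUARD]
    rows = []
    for mid, sub in guards.groupby("male_id", sort=False):
        first = sub.sort_values("age_years", kind="stable").iloc[0]
        rows.append({
            "male_id": mid,
            "group_id": first["group_id"],
            "first_guard_event": first["event_id"],
            "age_years": float(first["age_years"]),
            "weight_g": float(first["weight_g"]),
            "age_rank": int(first["age_rank"]),
            "group_centred_weight": float(first["group_centred_weight"]),
            "lrs": int(lrs_total.get(mid, 0)),
        })
    df = pd.DataFrame(rows)
    return df.dropna(subset=["group_centred_weight"]).reset_index(drop=True) if len(df) else df
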