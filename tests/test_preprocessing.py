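import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import socialstate as ss
from socialstate.preprocessing import (
    CovariateScaler,
    age_rank_vector,
    event_covariates,
)


class TestSummarizeEventState:
    @pytest.mark.parametrize(
        "records,expected",
        [
            (["none", "none", "none"], ss.SUBORDINATE),
            (["guard", "none", "none"], ss.GUARD),
            (["sneak", "sneak", "guard"], ss.SNEAKER),
            (["sneak", "guard"], ss.GUARD),           # tie: guarding wins
            (["sneak"], ss.SNEAKER),
            (["guard"] * 5, ss.GUARD),
        ],
    )
    def test_daily_records_collapse(self, records, expected):
        assert ss.summarize_event_state(records) == expected

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            ss.summarize_event_state([])

    def test_unknown_behaviour_rejected(self):
        with pytest.raises(ValueError):
            ss.summarize_event_state(["guard", "fly"])


class TestGroupCentredWeight:
    def test_arithmetic(self):
        assert ss.compute_group_centred_weight(1500, [1500, 1400, 1300]) == pytest.approx(100.0)

    def test_single_male_group_is_zero(self):
        assert ss.compute_group_centred_weight(1432.5, [1432.5]) == 0.0

    def test_uniform_group_is_zero(self):
        assert ss.compute_group_centred_weight(1456, [1456] * 7) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ss.compute_group_centred_weight(1500, [])

    def test_within_event_weights_sum_to_zero(self, small_bundle):
        cov = event_covariates(small_bundle.states, small_bundle.events,
                               small_bundle.males, small_bundle.weights)
        sums = cov.groupby("event_id")["group_centred_weight"].sum()
        assert np.allclose(sums, 0.0, atol=1e-9)


class TestAgeRank:
    def test_oldest_is_rank_one(self):
        assert ss.compute_age_rank([8, 5, 2], 0) == 1
        assert ss.compute_age_rank([8, 5, 2], 2) == 3

    def test_tie_broken_by_id(self):
        assert ss.compute_age_rank([4, 4], 1, ids=["A", "B"]) == 2
        assert ss.compute_age_rank([4, 4], 0, ids=["A", "B"]) == 1

    @given(st.lists(st.floats(min_value=1, max_value=15), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ranks_are_a_permutation(self, ages):
        ids = [f"M{i}" for i in range(len(ages))]
        ranks = age_rank_vector(ages, ids)
        assert sorted(ranks) == list(range(1, len(ages) + 1))


class TestStandardize:
    def test_zscore_property(self):
        z, _ = ss.standardize([-200.0, 0.0, 200.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_unit_interval_covariate_passes_through(self):
        z, scaler = ss.standardize([0.1, 0.5, 0.9])
        assert np.allclose(z, [0.1, 0.5, 0.9])
        assert not scaler.params["x"]["standardized"]

    def test_round_trip_identity(self):
        vals = np.array([3.0, -17.5, 42.1, 500.0])
        z, scaler = ss.standardize(vals)
        back = scaler.inverse_values("x", z)
        assert np.allclose(back, vals, atol=1e-12)

    def test_zero_variance_names_covariate(self):
        with pytest.raises(ValueError, match="age_rank"):
            CovariateScaler.fit(pd.DataFrame({"age_rank": [2.0, 2.0, 2.0]}), ["age_rank"])

    def test_json_round_trip(self, tmp_path):
        _, scaler = ss.standardize([-5.0, 0.0, 7.0], name="w")
        path = tmp_path / "scaler.json"
        scaler.to_json(path)
        again = CovariateScaler.from_json(path)
        assert again.params["w"] == pytest.approx(scaler.params["w"])


def _toy_tables():
    events = pd.DataFrame({
        "event_id": ["E0", "E1", "E2"],
        "group_id": ["G", "G", "G"],
        "start_date": ["2005-01-01", "2005-04-01", "2005-07-01"],
        "end_date": ["2005-01-08", "2005-04-08", "2005-07-08"],
    })
    males = pd.DataFrame({
        "male_id": ["A", "B", "C"],
        "group_id": ["G", "G", "G"],
        "birth_date": ["2001-01-01", "2002-06-01", "2003-01-01"],
        "death_date": ["2005-05-01", "2006-08-01", ""],  # B dies >365d after E1
    })
    states = pd.DataFrame({
        "male_id": ["A", "B", "C", "A", "B", "C", "C"],
        "event_id": ["E0", "E0", "E0", "E1", "E1", "E1", "E2"],
        "state": [ss.SUBORDINATE, ss.GUARD, ss.SUBORDINATE,
                  ss.GUARD, ss.GUARD, ss.SUBORDINATE, ss.GUARD],
    })
    weights = pd.DataFrame({
        "male_id": ["A", "B", "C"] * 3,
        "date": ["2004-12-28"] * 3 + ["2005-03-28"] * 3 + ["2005-06-28"] * 3,
        "weight_g": [1500.0, 1400.0, 1200.0] * 3,
    })
    states = states[~((states.male_id == "B") & (states.event_id == "E2"))]
    return states, events, males, weights


class TestBuildTransitionTable:
    def test_consecutive_pairs_and_death_handling(self):
        states, events, males, weights = _toy_tables()
        out = ss.build_transition_table(states, events, males, weights)
        # A: E0->E1 then dies 2005-05-01 (23d after E1 end, within the death
        # window); exposure runs to the group's next event E2 (2005-07-01)
        a = out[out.male_id == "A"]
        assert list(a.outcome) == [ss.GUARD, ss.DEAD]
        assert a.iloc[1]["interval_days"] == 84
        # B: dies 2006-08-01, >365d after last event E1 -> terminal dropped,
        # earlier interval kept
        b = out[out.male_id == "B"]
        assert list(b.outcome) == [ss.GUARD]
        assert out.attrs["n_late_death_censored"] == 1
        # C alive with 3 events -> 2 observations
        c = out[out.male_id == "C"]
        assert list(c.outcome) == [ss.SUBORDINATE, ss.GUARD]
        # interval indices are per-male counters starting at 0
        assert list(out.groupby("male_id")["interval_index"].min()) == [0, 0, 0]

    def test_single_event_male_contributes_nothing(self):
        states, events, males, weights = _toy_tables()
        states = states[states.male_id.isin(["A"]) | (states.event_id == "E0")]
        states = states[~((states.male_id != "A") & (states.event_id != "E0"))]
        out = ss.build_transition_table(states, events, males, weights)
        assert set(out.male_id) == {"A"}

    def test_filters_commute(self):
        # applying the >=2-event rule and the death window in either order
        # yields the same rows: the late-death male keeps his live intervals
        states, events, males, weights = _toy_tables()
        full = ss.build_transition_table(states, events, males, weights)
        # censor B's death first, then build: identical live rows
        males2 = males.copy()
        males2.loc[males2.male_id == "B", "death_date"] = ""
        alt = ss.build_transition_table(states, events, males2, weights)
        cols = ["male_id", "event_from", "event_to", "outcome"]
        assert full[cols].reset_index(drop=True).equals(alt[cols].reset_index(drop=True))

    def test_state_after_death_is_integrity_error(self):
        states, events, males, weights = _toy_tables()
        males.loc[males.male_id == "C", "death_date"] = "2005-05-01"  # before E2
        with pytest.raises(ValueError, match="after death"):
            ss.build_transition_table(states, events, males, weights)

    def test_origin_precedes_destination(self, small_designs):
        tr = small_designs["transitions"]
        assert (tr["interval_days"] >= 0).all()
        assert (tr["origin_state"] != ss.DEAD).all()


class TestLinkLitters:
    def test_gestation_window_examples(self):
        events = pd.DataFrame({
            "event_id": ["E0", "E1"],
            "group_id": ["G", "G"],
            "start_date": ["2000-02-03", "2000-02-13"],
            "end_date": ["2000-02-10", "2000-02-20"],  # days 40 and 50
        })
        litters = pd.DataFrame({
            "litter_id": ["L1", "L2"],
            "group_id": ["G", "G"],
            "birth_date": ["2000-04-10", "2000-03-01"],  # day 100 and day 60
        })
        out = ss.link_litters_to_events(litters, events).set_index("litter_id")
        # day 100: gaps are 60 and 50; |60-59| < |50-59| -> earlier event wins
        assert out.loc["L1", "event_id"] == "E0"
        # day 60: gaps 20 and 10, both below the 44-day window -> unlinked
        assert out.loc["L2", "event_id"] == ""

    def test_exact_modal_gap_links(self):
        events = pd.DataFrame({
            "event_id": ["E0"], "group_id": ["G"],
            "start_date": ["2000-02-03"], "end_date": ["2000-02-10"],
        })
        litters = pd.DataFrame({
            "litter_id": ["L"], "group_id": ["G"], "birth_date": ["2000-04-09"],
        })
        out = ss.link_litters_to_events(litters, events)
        assert out.loc[0, "gap_days"] == 59


class TestCollinearity:
    def test_identical_and_orthogonal_columns(self):
        df = pd.DataFrame({
            "a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, -1, -1, 1],
        })
        rep = ss.diagnose_collinearity(df, threshold=0.7).set_index(["var1", "var2"])
        assert rep.loc[("a", "b"), "r"] == pytest.approx(1.0)
        assert rep.loc[("a", "b"), "flagged"]
        assert rep.loc[("a", "c"), "r"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_reported_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        rep = ss.diagnose_collinearity(df)
        row = rep[(rep.var1 == "a") & (rep.var2 == "b")].iloc[0]
        assert np.isnan(row["r"]) and "undefined" in row["note"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ss.diagnose_collinearity(pd.DataFrame({"a": [1.0, 2]}))

    def test_simulator_output_report_finite(self, small_designs):
        rep = ss.diagnose_collinearity(
            small_designs["transitions"],
            columns=["age_years", "age_rank", "group_centred_weight", "interval_days"],
        )
        assert np.isfinite(rep["r"]).all()
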