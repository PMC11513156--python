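import math

import numpy as np
import pandas as pd
import pytest

import socialstate as ss
from socialstate.multistate_model import ModelSpec, standardized_true_params
from socialstate.preprocessing import CovariateScaler


def identity_scaler():
    cols = ["group_centred_weight", "age_rank", "age_years", "age_sq", "interval_days"]
    return CovariateScaler({c: {"centre": 0.0, "scale": 1.0, "standardized": False}
                            for c in cols})


def toy_transitions(n=12, seed=0, with_death=False):
    rng = np.random.default_rng(seed)
    outcomes = rng.integers(0, 3, n)
    if with_death:
        outcomes[0] = ss.DEAD
    return pd.DataFrame({
        "male_id": [f"M{i % 4}" for i in range(n)],
        "group_id": [f"G{i % 2}" for i in range(n)],
        "event_from": [f"E{i % 3}" for i in range(n)],
        "origin_state": rng.integers(0, 3, n),
        "outcome": outcomes,
        "age_years": rng.uniform(1, 10, n),
        "age_rank": rng.integers(1, 8, n),
        "group_centred_weight": rng.normal(0, 1.5, n),
        "interval_days": rng.uniform(60, 120, n),
    })


class TestTransitionLoglik:
    def test_symmetric_null(self):
        df = toy_transitions(9)
        ll = ss.transition_loglik({}, df, identity_scaler(), "age_rank")
        assert ll == pytest.approx(9 * math.log(1 / 3), abs=1e-12)

    def test_saturation_limit(self):
        df = toy_transitions(1)
        df.loc[0, ["origin_state", "outcome"]] = [ss.SUBORDINATE, ss.GUARD]
        ll = ss.transition_loglik({"subordinate>guard:intercept": 50.0},
                                  df, identity_scaler(), "age_rank")
        assert -1e-9 < ll <= 0.0

    def test_matches_bruteforce_oracle(self):
        df = toy_transitions(12, seed=3)
        params = {
            "subordinate>guard:intercept": -1.1,
            "subordinate>guard:group_centred_weight": 0.4,
            "subordinate>guard:age_rank": -0.2,
            "subordinate>sneaker:intercept": -2.5,
            "guard>guard:intercept": 0.3,
            "guard>guard:group_centred_weight": 0.5,
            "sneaker>guard:intercept": -0.7,
            "guard>sneaker:age_rank": 0.1,
        }
        re_vals = {
            "event": np.array([0.2, -0.1, 0.05]),
            "group": np.array([0.1, -0.3]),
            "male": np.array([0.0, 0.15, -0.2, 0.05]),
        }
        ll = ss.transition_loglik(params, df, identity_scaler(), "age_rank", re_vals)

        # explicit per-row softmax, summed by an independent loop
        ev_ix = {e: i for i, e in enumerate(pd.unique(df.event_from))}
        gr_ix = {g: i for i, g in enumerate(pd.unique(df.group_id))}
        ml_ix = {m: i for i, m in enumerate(pd.unique(df.male_id))}
        names = {0: "subordinate", 1: "sneaker", 2: "guard"}
        expected = 0.0
        for _, r in df.iterrows():
            re = (re_vals["event"][ev_ix[r.event_from]]
                  + re_vals["group"][gr_ix[r.group_id]]
                  + re_vals["male"][ml_ix[r.male_id]])
            eta = [0.0, 0.0, 0.0]
            for d in (1, 2):
                base = f"{names[r.origin_state]}>{names[d]}"
                eta[d] = (params.get(f"{base}:intercept", 0.0)
                          + params.get(f"{base}:group_centred_weight", 0.0) * r.group_centred_weight
                          + params.get(f"{base}:age_rank", 0.0) * r.age_rank
                          + re)
            denom = sum(math.exp(e) for e in eta)
            expected += math.log(math.exp(eta[int(r.outcome)]) / denom)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_dead_outcome_rejected(self):
        df = toy_transitions(6, with_death=True)
        with pytest.raises(ValueError, match="mortality"):
            ss.transition_loglik({}, df, identity_scaler(), "age_rank")

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            ss.transition_loglik({"nope": 1.0}, toy_transitions(5), identity_scaler(), "age_rank")


class TestMortalityLoglik:
    def test_all_zero_parameters(self):
        df = toy_transitions(10, with_death=True)
        ll = ss.mortality_loglik({}, df, identity_scaler(), "age_rank")
        assert ll == pytest.approx(10 * math.log(0.5), abs=1e-12)

    def test_immortal_limit(self):
        df = toy_transitions(8)  # no deaths
        params = {f"mort:{s}:intercept": -1e8 for s in ("subordinate", "sneaker", "guard")}
        ll = ss.mortality_loglik(params, df, identity_scaler(), "age_rank")
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_bernoulli_oracle(self):
        df = toy_transitions(10, seed=5, with_death=True)
        params = {
            "mort:subordinate:intercept": -2.0,
            "mort:guard:intercept": -1.5,
            "mort:sneaker:intercept": -2.2,
            "mort:guard:group_centred_weight": -0.5,
            "mort:age_rank": 0.1,
            "mort:interval_days": 0.02,
        }
        re_vals = {"group": np.array([0.2, -0.2])}
        ll = ss.mortality_loglik(params, df, identity_scaler(), "age_rank", re_vals)
        gr_ix = {g: i for i, g in enumerate(pd.unique(df.group_id))}
        names = {0: "subordinate", 1: "sneaker", 2: "guard"}
        expected = 0.0
        for _, r in df.iterrows():
            s = names[r.origin_state]
            eta = (params[f"mort:{s}:intercept"]
                   + params.get(f"mort:{s}:group_centred_weight", 0.0) * r.group_centred_weight
                   + params["mort:age_rank"] * r.age_rank
                   + params["mort:interval_days"] * r.interval_days
                   + re_vals["group"][gr_ix[r.group_id]])
            p = 1.0 / (1.0 + math.exp(-eta))
            expected += math.log(p if r.outcome == ss.DEAD else 1.0 - p)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_negative_interval_rejected(self):
        df = toy_transitions(5)
        df.loc[2, "interval_days"] = -1
        with pytest.raises(ValueError, match="interval"):
            ss.mortality_loglik({}, df, identity_scaler(), "age_rank")


class TestTransitionMatrix:
    COV = {"group_centred_weight": 0.0, "age_rank": 3, "interval_days": 91}

    def test_dead_row_absorbing_and_null_composition(self):
        mat = ss.transition_matrix_at({}, {}, self.COV, identity_scaler(), "age_rank")
        assert np.allclose(mat[ss.DEAD], [0, 0, 0, 1])
        for s in (ss.SUBORDINATE, ss.SNEAKER, ss.GUARD):
            assert np.allclose(mat[s], [0.5 / 3, 0.5 / 3, 0.5 / 3, 0.5], atol=1e-12)

    def test_rows_sum_to_one_for_random_parameters(self):
        rng = np.random.default_rng(8)
        scaler = identity_scaler()
        names = {0: "subordinate", 1: "sneaker", 2: "guard"}
        for _ in range(20):
            tp = {f"{names[o]}>{names[d]}:{c}": rng.normal()
                  for o in range(3) for d in (1, 2)
                  for c in ("intercept", "group_centred_weight", "age_rank")}
            mp = {f"mort:{names[s]}:{c}": rng.normal()
                  for s in range(3) for c in ("intercept", "group_centred_weight")}
            mp["mort:age_rank"] = rng.normal()
            mp["mort:interval_days"] = rng.normal()
            cov = {"group_centred_weight": rng.normal(0, 200), "age_rank": 4,
                   "interval_days": 91}
            mat = ss.transition_matrix_at(tp, mp, cov, scaler, "age_rank")
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((mat >= 0) & (mat <= 1))

    def test_composition_matches_independent_oracle(self):
        tp = {"subordinate>guard:intercept": -1.0,
              "subordinate>guard:group_centred_weight": 0.005,
              "subordinate>sneaker:intercept": -2.7}
        mp = {"mort:subordinate:intercept": -2.5,
              "mort:subordinate:group_centred_weight": 0.001,
              "mort:sneaker:intercept": -2.5, "mort:sneaker:group_centred_weight": 0.0,
              "mort:guard:intercept": -2.4, "mort:guard:group_centred_weight": -0.004,
              "mort:age_rank": -0.03, "mort:interval_days": 0.005}
        cov = {"group_centred_weight": 120.0, "age_rank": 2, "interval_days": 80}
        mat = ss.transition_matrix_at(tp, mp, cov, identity_scaler(), "age_rank")
        eta_m = -2.5 + 0.001 * 120 - 0.03 * 2 + 0.005 * 80
        p_dead = 1 / (1 + math.exp(-eta_m))
        eta_k = -2.7
        eta_g = -1.0 + 0.005 * 120
        z = 1 + math.exp(eta_k) + math.exp(eta_g)
        expected = [(1 - p_dead) / z, (1 - p_dead) * math.exp(eta_k) / z,
                    (1 - p_dead) * math.exp(eta_g) / z, p_dead]
        assert np.allclose(mat[ss.SUBORDINATE], expected, atol=1e-12)

    def test_sub_to_guard_monotone_in_weight_under_positive_slope(self):
        tp = {"subordinate>guard:intercept": -1.2,
              "subordinate>guard:group_centred_weight": 0.005,
              "subordinate>sneaker:intercept": -2.7}
        mp = {f"mort:{s}:intercept": -2.5 for s in ("subordinate", "sneaker", "guard")}
        mp |= {f"mort:{s}:group_centred_weight": 0.0 for s in ("subordinate", "sneaker", "guard")}
        probs = [
            ss.transition_matrix_at(
                tp, mp, {"group_centred_weight": w, "age_rank": 3, "interval_days": 91},
                identity_scaler(), "age_rank")[ss.SUBORDINATE, ss.GUARD]
            for w in np.linspace(-300, 300, 13)
        ]
        assert np.all(np.diff(probs) > 0)

    def test_missing_scaler_rejected(self):
        with pytest.raises(ValueError, match="scaler"):
            ss.transition_matrix_at({}, {}, self.COV, None, "age_rank")


class TestModelSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("transition", "age_rank", chains=1)
        with pytest.raises(ValueError):
            ModelSpec("transition", "age_rank", iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ModelSpec("transition", "cubic_age")
        with pytest.raises(ValueError):
            ModelSpec("divination", "age_rank")
        with pytest.raises(ValueError):
            ModelSpec("transition", "age_rank", thin=0)

    def test_empty_table_rejected(self):
        spec = ModelSpec("transition", "age_rank", iterations=100, burn_in=10)
        with pytest.raises(ValueError, match="empty"):
            ss.fit_mcmc(spec, toy_transitions(0), identity_scaler())


class TestTrueParamMapping:
    def test_identity_scaler_returns_raw_coefficients(self):
        tp = ss.TrueParams(variant="age_rank")
        out = standardized_true_params(tp, identity_scaler(), "age_rank", "transition")
        c = tp.transition_age_rank[(ss.SUBORDINATE, ss.GUARD)]
        assert out["subordinate>guard:intercept"] == pytest.approx(c["intercept"])
        assert out["subordinate>guard:group_centred_weight"] == pytest.approx(c["weight"])
        assert out["subordinate>guard:age_rank"] == pytest.approx(c["rank"])
        mo = standardized_true_params(tp, identity_scaler(), "age_rank", "mortality")
        assert mo["mort:guard:group_centred_weight"] == pytest.approx(
            tp.mortality_age_rank["beta_weight"][ss.GUARD])

    def test_scaling_maps_slopes_linearly(self):
        scaler = identity_scaler()
        scaler.params["group_centred_weight"] = {"centre": 10.0, "scale": 100.0,
                                                 "standardized": True}
        tp = ss.TrueParams(variant="age_rank")
        out = standardized_true_params(tp, scaler, "age_rank", "transition")
        c = tp.transition_age_rank[(ss.SUBORDINATE, ss.GUARD)]
        assert out["subordinate>guard:group_centred_weight"] == pytest.approx(c["weight"] * 100)
        assert out["subordinate>guard:intercept"] == pytest.approx(
            c["intercept"] + c["weight"] * 10.0)
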