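"""Two-part discrete-time multistate model of reproductive roles and death.

Per oestrus-event interval the outcome law factorizes as

    P(dead)        = logit^-1( alpha_s + beta_s * w + age term + gamma * dt + REs )
    P(dest | live) = multinomial logit over {subordinate, sneaker, guard}
                     with subordinate as reference destination,

with origin-state-specific coefficients, two covariate variants (within-group
age rank, or quadratic absolute age; group-centred weight ``w`` is always
included), and crossed Gaussian random effects for oestrus event, group and
male identity.  The two submodels are fitted separately; the full 4x4
transition matrix (rows S, K, G, dead) is composed only at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import block_diag
from scipy.special import log_expit

from .codes import DEAD, GUARD, LIVE_STATES, SNEAKER, STATE_NAMES, SUBORDINATE
from .mcmc import (
    Block,
    HierarchicalModel,
    PosteriorDraws,
    REFactor,
    design_preconditioner,
    rhat,
    sample_posterior,
)
from .preprocessing import CovariateScaler

VARIANTS = ("age_rank", "quadratic_age")
SUBMODELS = ("transition", "mortality")

#: default chain settings mirroring the original analyses
TRANSITION_MCMC = {"chains": 3, "iterations": 20_000, "burn_in": 2_000, "thin": 100}
MORTALITY_MCMC = {"chains": 3, "iterations": 50_000, "burn_in": 5_000, "thin": 100}

RE_COLUMNS = {"event": "event_from", "group": "group_id", "male": "male_id"}


def variant_covariates(variant: str) -> list[str]:
    if variant == "age_rank":
        return ["age_rank"]
    if variant == "quadratic_age":
        return ["age_years", "age_sq"]
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class ModelSpec:
    """Specification of one submodel fit."""

    submodel: str
    variant: str
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 100
    seed: int = 0
    fixed_prior_sd: float = 2.5
    re_prior_scale: float = 1.0
    time_interactions: bool = False   # interval x covariate terms, mortality only
    # The two-event inclusion rule means a death can never be observed in a
    # male's first interval (such males are filtered out entirely), so those
    # structurally death-free rows are dropped from the mortality likelihood.
    drop_first_interval: bool = True

    def __post_init__(self) -> None:
        if self.submodel not in SUBMODELS:
            raise ValueError(f"unknown submodel {self.submodel!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")


def _prepare(table: pd.DataFrame, scaler: CovariateScaler) -> pd.DataFrame:
    df = table.copy()
    if "age_sq" not in df:
        df["age_sq"] = df["age_years"] ** 2
    return scaler.transform(df)


def _re_factors(df: pd.DataFrame, prior_scale: float) -> list[REFactor]:
    factors = []
    for name, col in RE_COLUMNS.items():
        codes, levels = pd.factorize(df[col])
        factors.append(REFactor(name, codes.astype(int), len(levels), prior_scale))
    return factors


# ---------------------------------------------------------------------------
# Transition submodel (conditional on survival)
# ---------------------------------------------------------------------------

class TransitionModel(HierarchicalModel):
    """Multinomial-logit destination model for survivors.

    Parameters are origin-state specific: for each origin s and non-reference
    destination d in {sneaker, guard}, an intercept plus slopes on the
    (standardized) covariates.  One shared random effect per (event, group,
    male) level is added to both non-reference destination predictors.
    """

    def __init__(self, table: pd.DataFrame, variant: str, scaler: CovariateScaler,
                 fixed_prior_sd: float = 2.5, re_prior_scale: float = 1.0):
        if (table["outcome"] == DEAD).any():
            raise ValueError(
                "transition submodel takes survivor rows only; dead outcomes "
                "belong to the mortality submodel"
            )
        df = _prepare(table, scaler)
        self.variant = variant
        self.columns = ["intercept", "group_centred_weight"] + variant_covariates(variant)
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in self.columns[1:]]
        )
        self.X = X
        self.ncol = X.shape[1]
        self.origin = df["origin_state"].to_numpy(dtype=int)
        self.y = df["outcome"].to_numpy(dtype=int)
        self.n_rows = len(df)

        self.theta_names = [
            f"{STATE_NAMES[o]}>{STATE_NAMES[d]}:{c}"
            for o in LIVE_STATES for d in (SNEAKER, GUARD) for c in self.columns
        ]
        n_theta = len(self.theta_names)
        self.prior_mean = np.zeros(n_theta)
        self.prior_sd = np.full(n_theta, fixed_prior_sd)

        self.blocks = []
        per_origin = 2 * self.ncol
        self._origin_rows = []
        for o in LIVE_STATES:
            rows = np.flatnonzero(self.origin == o)
            self._origin_rows.append(rows)
            Xo = X[rows] if len(rows) else X[:1]
            chol = design_preconditioner(Xo)
            self.blocks.append(Block(
                indices=np.arange(o * per_origin, (o + 1) * per_origin),
                rows=rows,
                prop_chol=block_diag(chol, chol) * (2.38 / np.sqrt(per_origin)),
            ))
        self._X_by_origin = [X[r] for r in self._origin_rows]
        self.re_factors = _re_factors(df, re_prior_scale)
        # one intercept per (origin, destination): trades off against a
        # constant shift of any shared random-effect field
        self.intercept_indices = np.array(
            [i for i, n in enumerate(self.theta_names) if n.endswith(":intercept")]
        )

    def linear_predictors(self, theta, re_row, rows=None):
        """(eta_sneaker, eta_guard) per row; reference destination has eta 0."""
        B = np.asarray(theta).reshape(3, 2, self.ncol)
        if rows is None:
            eta_k = np.empty(self.n_rows)
            eta_g = np.empty(self.n_rows)
            for o, (r, Xo) in enumerate(zip(self._origin_rows, self._X_by_origin)):
                eta_k[r] = Xo @ B[o, 0, :]
                eta_g[r] = Xo @ B[o, 1, :]
            return eta_k + re_row, eta_g + re_row
        X, origin, re = self.X[rows], self.origin[rows], re_row[rows]
        eta_k = np.einsum("ij,ij->i", X, B[origin, 0, :]) + re
        eta_g = np.einsum("ij,ij->i", X, B[origin, 1, :]) + re
        return eta_k, eta_g

    def loglik_rows(self, theta, re_row, rows=None):
        eta_k, eta_g = self.linear_predictors(theta, re_row, rows)
        y = self.y if rows is None else self.y[rows]
        eta = np.column_stack([np.zeros_like(eta_k), eta_k, eta_g])
        m = eta.max(axis=1)
        denom = m + np.log(np.exp(eta - m[:, None]).sum(axis=1))
        return eta[np.arange(len(y)), y] - denom


# ---------------------------------------------------------------------------
# Mortality submodel
# ---------------------------------------------------------------------------

class MortalityModel(HierarchicalModel):
    """Bernoulli death-before-next-event model.

    State-specific intercepts and weight slopes (the state x weight structure
    behind condition-dependent mortality of guards), a shared age or age-rank
    slope, and an interval-length slope; crossed random effects as above.
    """

    def __init__(self, table: pd.DataFrame, variant: str, scaler: CovariateScaler,
                 fixed_prior_sd: float = 2.5, re_prior_scale: float = 1.0,
                 time_interactions: bool = False):
        if (table["interval_days"] < 0).any():
            raise ValueError("interval_days must be non-negative")
        df = _prepare(table, scaler)
        self.variant = variant
        origin = df["origin_state"].to_numpy(dtype=int)
        w = df["group_centred_weight"].to_numpy(dtype=float)
        dt = df["interval_days"].to_numpy(dtype=float)
        age_cols = variant_covariates(variant)

        cols, names = [], []
        for s in LIVE_STATES:
            cols.append((origin == s).astype(float))
            names.append(f"mort:{STATE_NAMES[s]}:intercept")
        for s in LIVE_STATES:
            cols.append((origin == s) * w)
            names.append(f"mort:{STATE_NAMES[s]}:group_centred_weight")
        for c in age_cols:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(f"mort:{c}")
        cols.append(dt)
        names.append("mort:interval_days")
        if time_interactions:
            cols.append(dt * w)
            names.append("mort:interval_days:group_centred_weight")
            for c in age_cols:
                cols.append(dt * df[c].to_numpy(dtype=float))
                names.append(f"mort:interval_days:{c}")

        self.X = np.column_stack(cols)
        self.y = (df["outcome"] == DEAD).to_numpy(dtype=float)
        self.n_rows = len(df)
        self.theta_names = names
        self.prior_mean = np.zeros(len(names))
        self.prior_sd = np.full(len(names), fixed_prior_sd)
        self.blocks = [Block(
            indices=np.arange(len(names)),
            rows=None,
            prop_chol=design_preconditioner(self.X) * (2.38 / np.sqrt(len(names))),
        )]
        self.re_factors = _re_factors(df, re_prior_scale)
        self.intercept_indices = np.arange(3)

    def loglik_rows(self, theta, re_row, rows=None):
        if rows is None:
            X, y, re = self.X, self.y, re_row
        else:
            X, y, re = self.X[rows], self.y[rows], re_row[rows]
        eta = X @ np.asarray(theta) + re
        return y * log_expit(eta) + (1.0 - y) * log_expit(-eta)


# ---------------------------------------------------------------------------
# Functional log-likelihood operations (oracle-checkable)
# ---------------------------------------------------------------------------

def _re_row_from_values(model: HierarchicalModel, re_values: dict | None) -> np.ndarray:
    re_row = np.zeros(model.n_rows)
    if re_values:
        for f in model.re_factors:
            if f.name in re_values:
                re_row = re_row + np.asarray(re_values[f.name])[f.codes]
    return re_row


def _theta_from_dict(model: HierarchicalModel, params: dict) -> np.ndarray:
    unknown = set(params) - set(model.theta_names)
    if unknown:
        raise KeyError(f"unknown parameter names: {sorted(unknown)}")
    return np.array([params.get(n, 0.0) for n in model.theta_names])


def transition_loglik(params: dict, table: pd.DataFrame, scaler: CovariateScaler,
                      variant: str, re_values: dict | None = None) -> float:
    """Log-likelihood of observed live destinations under a parameter map.

    ``params`` maps parameter names (``"subordinate>guard:intercept"`` etc.)
    to values on the standardized scale; unnamed parameters default to 0.
    ``re_values`` optionally maps factor name to per-level effect values.
    """
    model = TransitionModel(table, variant, scaler)
    theta = _theta_from_dict(model, params)
    return float(model.loglik_rows(theta, _re_row_from_values(model, re_values)).sum())


def mortality_loglik(params: dict, table: pd.DataFrame, scaler: CovariateScaler,
                     variant: str, re_values: dict | None = None) -> float:
    """Bernoulli log-likelihood of death outcomes under a parameter map."""
    model = MortalityModel(table, variant, scaler)
    theta = _theta_from_dict(model, params)
    return float(model.loglik_rows(theta, _re_row_from_values(model, re_values)).sum())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_mcmc(spec: ModelSpec, table: pd.DataFrame, scaler: CovariateScaler) -> PosteriorDraws:
    """Fit one submodel per its spec and return labelled posterior draws."""
    if len(table) == 0:
        raise ValueError("design table is empty")
    if spec.submodel == "transition":
        live = table[table["outcome"] != DEAD]
        model = TransitionModel(live, spec.variant, scaler,
                                spec.fixed_prior_sd, spec.re_prior_scale)
    else:
        mt = table
        if spec.drop_first_interval and "interval_index" in mt.columns:
            mt = mt[mt["interval_index"] > 0]
        model = MortalityModel(mt, spec.variant, scaler,
                               spec.fixed_prior_sd, spec.re_prior_scale,
                               spec.time_interactions)
    draws = sample_posterior(model, spec.chains, spec.iterations,
                             spec.burn_in, spec.thin, spec.seed)
    draws.meta.update({"submodel": spec.submodel, "variant": spec.variant})
    return draws


def fit_transition(table, variant, scaler, **kw) -> PosteriorDraws:
    settings = {**TRANSITION_MCMC, **kw}
    return fit_mcmc(ModelSpec("transition", variant, **settings), table, scaler)


def fit_mortality(table, variant, scaler, **kw) -> PosteriorDraws:
    settings = {**MORTALITY_MCMC, **kw}
    return fit_mcmc(ModelSpec("mortality", variant, **settings), table, scaler)


# ---------------------------------------------------------------------------
# Composed transition matrix
# ---------------------------------------------------------------------------

def _covariate_vector(columns: list[str], covariates: dict, scaler: CovariateScaler):
    x = [1.0]
    cov = dict(covariates)
    if "age_years" in columns and "age_sq" not in cov and "age_years" in cov:
        cov["age_sq"] = cov["age_years"] ** 2
    for c in columns[1:]:
        x.append(float(scaler.transform_values(c, [cov[c]])[0]))
    return np.asarray(x)


def transition_matrix_at(trans_params: dict, mort_params: dict, covariates: dict,
                         scaler: CovariateScaler, variant: str) -> np.ndarray:
    """Population-level 4x4 transition matrix at raw-scale covariate values.

    Rows and columns are ordered (subordinate, sneaker, guard, dead); random
    effects are set to zero; the dead row is absorbing.  Each live row
    composes the mortality probability with the conditional multinomial over
    live destinations, so rows sum to one by construction.
    """
    if scaler is None:
        raise ValueError("a fitted covariate scaler is required")
    columns = ["intercept", "group_centred_weight"] + variant_covariates(variant)
    x = _covariate_vector(columns, covariates, scaler)

    mat = np.zeros((4, 4))
    mat[DEAD, DEAD] = 1.0
    cov = dict(covariates)
    if variant == "quadratic_age" and "age_sq" not in cov:
        cov["age_sq"] = cov["age_years"] ** 2
    mort_cols = (
        [f"mort:{STATE_NAMES[s]}:intercept" for s in LIVE_STATES],
        [f"mort:{STATE_NAMES[s]}:group_centred_weight" for s in LIVE_STATES],
    )
    w_std = x[1]
    age_std = x[2:]
    age_names = [f"mort:{c}" for c in variant_covariates(variant)]
    dt_std = float(scaler.transform_values("interval_days", [cov["interval_days"]])[0]) \
        if "interval_days" in cov else 0.0

    for s in LIVE_STATES:
        eta_m = (
            mort_params.get(mort_cols[0][s], 0.0)
            + mort_params.get(mort_cols[1][s], 0.0) * w_std
            + sum(mort_params.get(n, 0.0) * a for n, a in zip(age_names, age_std))
            + mort_params.get("mort:interval_days", 0.0) * dt_std
        )
        p_dead = 1.0 / (1.0 + np.exp(-eta_m))
        eta = np.zeros(3)
        for d in (SNEAKER, GUARD):
            eta[d] = sum(
                trans_params.get(f"{STATE_NAMES[s]}>{STATE_NAMES[d]}:{c}", 0.0) * xv
                for c, xv in zip(columns, x)
            )
        eta -= eta.max()
        live = np.exp(eta) / np.exp(eta).sum()
        mat[s, :3] = (1.0 - p_dead) * live
        mat[s, DEAD] = p_dead
    return mat


# ---------------------------------------------------------------------------
# Mapping generative (raw-scale) truth onto the standardized fitted scale
# ---------------------------------------------------------------------------

def standardized_true_params(true_params, scaler: CovariateScaler, variant: str,
                             submodel: str) -> dict:
    """Express the simulator's raw-scale coefficients on the fitted scale.

    Standardizing a covariate x -> (x - m)/s turns a raw slope b into b*s and
    shifts the intercept by b*m; this returns the fitted-parameter map whose
    posterior should concentrate near these values in a recovery study.
    """
    def ms(name):
        p = scaler.params[name]
        return p["centre"], p["scale"]

    out = {}
    raw_cov = {"group_centred_weight": "weight"}
    if variant == "age_rank":
        raw_cov.update({"age_rank": "rank"})
    else:
        raw_cov.update({"age_years": "age", "age_sq": "age2"})

    if submodel == "transition":
        coeffs = (true_params.transition_age_rank if variant == "age_rank"
                  else true_params.transition_quadratic_age)
        for (o, d), c in coeffs.items():
            base = f"{STATE_NAMES[o]}>{STATE_NAMES[d]}"
            intercept = c["intercept"]
            for col, key in raw_cov.items():
                m, s = ms(col)
                out[f"{base}:{col}"] = c.get(key, 0.0) * s
                intercept += c.get(key, 0.0) * m
            out[f"{base}:intercept"] = intercept
    else:
        mc = (true_params.mortality_age_rank if variant == "age_rank"
              else true_params.mortality_quadratic_age)
        m_w, s_w = ms("group_centred_weight")
        m_dt, s_dt = ms("interval_days")
        shared_shift = mc["interval"] * m_dt
        for col, key in raw_cov.items():
            if col == "group_centred_weight":
                continue
            m, s = ms(col)
            out[f"mort:{col}"] = mc.get(key, 0.0) * s
            shared_shift += mc.get(key, 0.0) * m
        out["mort:interval_days"] = mc["interval"] * s_dt
        for s_state in LIVE_STATES:
            name = STATE_NAMES[s_state]
            out[f"mort:{name}:group_centred_weight"] = mc["beta_weight"][s_state] * s_w
            out[f"mort:{name}:intercept"] = (
                mc["alpha"][s_state] + mc["beta_weight"][s_state] * m_w + shared_shift
            )
    return out
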