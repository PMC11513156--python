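"""Companion fitness regressions around the multistate model.

* per-oestrus-event paternity share: binomial GLMM on the logit scale, with
  the event's total assigned pups as the number of trials;
* oestrus weight change: Gaussian model contrasting guards with subordinates;
* lifetime reproductive success (LRS): zero-inflated negative binomial
  regression on the covariates at first guarding activity.

All three reuse the adaptive Metropolis-within-Gibbs engine and the crossed
random-effect structure (event, group, male; group only for LRS).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, log_expit
from .codes import GUARD, SUBORDINATE
from .mcmc import (
    Block,
    HierarchicalModel,
    PosteriorDraws,
    REFactor,
    design_preconditioner,
    sample_posterior,
)
from .preprocessing import CovariateScaler

EVENT_MCMC = {"chains": 3, "iterations": 20_000, "burn_in": 2_000, "thin": 100}


def _kw(kw):
    return {**EVENT_MCMC, **kw}


# ---------------------------------------------------------------------------
# Paternity share (binomial)
# ---------------------------------------------------------------------------

def _paternity_columns(variant: str | None) -> list[str]:
    cols = ["group_centred_weight"]
    if variant == "age_rank":
        cols.append("age_rank")
    elif variant == "quadratic_age":
        cols += ["age_years", "age_sq"]
    elif variant is not None:
        raise ValueError(f"unknown variant {variant!r}")
    return cols


class PaternityModel(HierarchicalModel):
    """Binomial model of pups sired out of the event total."""

    def __init__(self, table: pd.DataFrame, scaler: CovariateScaler,
                 variant: str | None = "age_rank", fixed_prior_sd: float = 2.5,
                 re_prior_scale: float = 1.0):
        if (table["sired"] > table["event_total"]).any():
            raise ValueError("sired count exceeds the event total")
        if (table["event_total"] < 1).any():
            raise ValueError("event_total must be >= 1")
        df = table.copy()
        if "age_sq" not in df and "age_years" in df:
            df["age_sq"] = df["age_years"] ** 2
        df = scaler.transform(df)
        cols = _paternity_columns(variant)
        self.X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
        )
        self.k = table["sired"].to_numpy(dtype=float)
        self.n = table["event_total"].to_numpy(dtype=float)
        self._const = gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1)
        self.n_rows = len(df)
        self.theta_names = ["pat:intercept"] + [f"pat:{c}" for c in cols]
        self.prior_mean = np.zeros(len(self.theta_names))
        self.prior_sd = np.full(len(self.theta_names), fixed_prior_sd)
        self.blocks = [Block(
            indices=np.arange(len(self.theta_names)), rows=None,
            prop_chol=design_preconditioner(self.X) * (2.38 / np.sqrt(self.X.shape[1])),
        )]
        codes_e, lev_e = pd.factorize(df["event_id"])
        codes_g, lev_g = pd.factorize(df["group_id"])
        codes_m, lev_m = pd.factorize(df["male_id"])
        self.re_factors = [
            REFactor("event", codes_e.astype(int), len(lev_e), re_prior_scale),
            REFactor("group", codes_g.astype(int), len(lev_g), re_prior_scale),
            REFactor("male", codes_m.astype(int), len(lev_m), re_prior_scale),
        ]
        self.intercept_indices = np.array([0])

    def loglik_rows(self, theta, re_row, rows=None):
        if rows is None:
            X, k, n, const, re = self.X, self.k, self.n, self._const, re_row
        else:
            X, k, n = self.X[rows], self.k[rows], self.n[rows]
            const, re = self._const[rows], re_row[rows]
        eta = X @ np.asarray(theta) + re
        return const + k * log_expit(eta) + (n - k) * log_expit(-eta)


def paternity_loglik(params: dict, table: pd.DataFrame, scaler: CovariateScaler,
                     variant: str | None = "age_rank",
                     re_values: dict | None = None) -> float:
    """Binomial log-likelihood of paternity observations under a parameter map."""
    model = PaternityModel(table, scaler, variant)
    theta = np.array([params.get(nm, 0.0) for nm in model.theta_names])
    unknown = set(params) - set(model.theta_names)
    if unknown:
        raise KeyError(f"unknown parameter names: {sorted(unknown)}")
    re_row = np.zeros(model.n_rows)
    if re_values:
        for f in model.re_factors:
            if f.name in re_values:
                re_row = re_row + np.asarray(re_values[f.name])[f.codes]
    return float(model.loglik_rows(theta, re_row).sum())


def paternity_fit(table: pd.DataFrame, scaler: CovariateScaler,
                  variant: str | None = "age_rank", seed: int = 0, **kw) -> PosteriorDraws:
    model = PaternityModel(table, scaler, variant)
    draws = sample_posterior(model, seed=seed, **_kw(kw))
    draws.meta.update({"submodel": "paternity", "variant": variant})
    return draws


# ---------------------------------------------------------------------------
# Oestrus weight change (Gaussian)
# ---------------------------------------------------------------------------

class WeightChangeModel(HierarchicalModel):
    """Gaussian model of percentage weight change: subordinate vs guard."""

    theta_layout = ("wc:subordinate_mean", "wc:guard_contrast", "wc:log_sigma")

    def __init__(self, table: pd.DataFrame, fixed_prior_sd: float = 10.0,
                 re_prior_scale: float = 1.0):
        states = set(table["state"].unique())
        if not states <= {SUBORDINATE, GUARD}:
            raise ValueError("weight-change model compares subordinates and guards only")
        if len(states) < 2:
            raise ValueError("both states must be present")
        if (table["pct_change"] <= -100).any():
            raise ValueError("pct_change must exceed -100")
        self.y = table["pct_change"].to_numpy(dtype=float)
        self.g = (table["state"] == GUARD).to_numpy(dtype=float)
        self.n_rows = len(table)
        self.theta_names = list(self.theta_layout)
        self.prior_mean = np.zeros(3)
        self.prior_sd = np.array([fixed_prior_sd, fixed_prior_sd, 1.5])
        Xmean = np.column_stack([np.ones(self.n_rows), self.g])
        self.blocks = [
            Block(np.array([0, 1]), None,
                  design_preconditioner(Xmean) * (2.38 / np.sqrt(2))),
            Block(np.array([2]), None, np.eye(1) * 0.3),
        ]
        codes_e, lev_e = pd.factorize(table["event_id"])
        codes_g, lev_g = pd.factorize(table["group_id"])
        codes_m, lev_m = pd.factorize(table["male_id"])
        self.re_factors = [
            REFactor("event", codes_e.astype(int), len(lev_e), re_prior_scale),
            REFactor("group", codes_g.astype(int), len(lev_g), re_prior_scale),
            REFactor("male", codes_m.astype(int), len(lev_m), re_prior_scale),
        ]
        self.intercept_indices = np.array([0])

    def loglik_rows(self, theta, re_row, rows=None):
        mu0, delta, log_sigma = np.asarray(theta)
        if rows is None:
            y, g, re = self.y, self.g, re_row
        else:
            y, g, re = self.y[rows], self.g[rows], re_row[rows]
        sigma = np.exp(log_sigma)
        z = (y - (mu0 + delta * g + re)) / sigma
        return -0.5 * z * z - log_sigma - 0.5 * np.log(2.0 * np.pi)


def weightchange_fit(table: pd.DataFrame, seed: int = 0, **kw) -> PosteriorDraws:
    """Posterior for subordinate mean, guard-subordinate contrast and SDs."""
    model = WeightChangeModel(table)
    draws = sample_posterior(model, seed=seed, **_kw(kw))
    draws.meta.update({"submodel": "weightchange"})
    return draws


def weightchange_report(draws: PosteriorDraws) -> dict:
    """Posterior means/CIs plus the qualitative guard-vs-subordinate contrast."""
    mu0 = draws.param("wc:subordinate_mean")
    delta = draws.param("wc:guard_contrast")
    guard = mu0 + delta
    lo_g, hi_g = np.percentile(guard, [2.5, 97.5])
    lo_s, hi_s = np.percentile(mu0, [2.5, 97.5])
    lo_d, hi_d = np.percentile(delta, [2.5, 97.5])
    return {
        "subordinate_mean": float(mu0.mean()),
        "subordinate_ci": (float(lo_s), float(hi_s)),
        "guard_mean": float(guard.mean()),
        "guard_ci": (float(lo_g), float(hi_g)),
        "contrast_mean": float(delta.mean()),
        "contrast_ci": (float(lo_d), float(hi_d)),
        "guard_ci_excludes_zero": bool(hi_g < 0 or lo_g > 0),
        "subordinate_ci_spans_zero": bool(lo_s <= 0 <= hi_s),
    }


# ---------------------------------------------------------------------------
# Zero-inflated negative binomial LRS
# ---------------------------------------------------------------------------

def zinb_logpmf(k, pi, mu, phi):
    """Zero-inflated negative binomial log-pmf.

    The count component is parameterized by mean ``mu`` and dispersion
    ``phi`` (variance mu + mu^2/phi, success probability phi/(phi+mu)):

        P(0)   = pi + (1-pi) * NB(0; mu, phi)
        P(k>0) = (1-pi) * NB(k; mu, phi)

    Accepts scalars or arrays; ``k`` must be a non-negative integer.
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    if np.any((np.asarray(pi) < 0) | (np.asarray(pi) > 1)):
        raise ValueError("pi must lie in [0, 1]")
    if np.any(np.asarray(mu) <= 0) or np.any(np.asarray(phi) <= 0):
        raise ValueError("mu and phi must be positive")
    k_arr, pi_arr, mu_arr, phi_arr = np.broadcast_arrays(
        k_arr, np.asarray(pi, float), np.asarray(mu, float), np.asarray(phi, float)
    )
    log_nb = (
        gammaln(k_arr + phi_arr) - gammaln(phi_arr) - gammaln(k_arr + 1)
        + phi_arr * np.log(phi_arr / (phi_arr + mu_arr))
        + k_arr * np.log(mu_arr / (phi_arr + mu_arr))
    )
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_arr)
        log_1mpi = np.log1p(-pi_arr)
    zero_case = np.logaddexp(log_pi, log_1mpi + phi_arr * np.log(phi_arr / (phi_arr + mu_arr)))
    out = np.where(k_arr == 0, zero_case, log_1mpi + log_nb)
    return float(out) if out.ndim == 0 else out


LRS_COVARIATES = {
    "relative": ["age_rank", "group_centred_weight"],
    "absolute": ["age_years", "weight_g"],
}


class LRSModel(HierarchicalModel):
    """ZINB regression of lifetime reproductive success.

    Zero-inflation is intercept-only; the count mean is log-linear in the
    covariates at first guarding with a group random intercept.
    """

    def __init__(self, table: pd.DataFrame, variant: str = "relative",
                 scaler: CovariateScaler | None = None, fixed_prior_sd: float = 2.5,
                 re_prior_scale: float = 1.0):
        if variant not in LRS_COVARIATES:
            raise ValueError(f"unknown LRS variant {variant!r}")
        y = table["lrs"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 distinct LRS values")
        if np.all(y == 0):
            raise ValueError("all-zero LRS: count component unidentifiable")
        cols = [c for c in LRS_COVARIATES[variant] if c in table.columns]
        if scaler is None:
            scaler = CovariateScaler.fit(table, cols)
        self.scaler = scaler
        df = scaler.transform(table)
        self.X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
        )
        self.y = y
        self.n_rows = len(df)
        self.columns = cols
        self.theta_names = (
            ["lrs:zero_logit", "lrs:intercept"]
            + [f"lrs:{c}" for c in cols] + ["lrs:log_phi"]
        )
        p = len(self.theta_names)
        self.prior_mean = np.zeros(p)
        self.prior_sd = np.full(p, fixed_prior_sd)
        self.prior_sd[-1] = 1.5
        count_idx = np.arange(1, p - 1)
        self.blocks = [
            Block(np.array([0]), None, np.eye(1) * 0.8),
            Block(count_idx, None,
                  design_preconditioner(self.X) * (2.38 / np.sqrt(len(count_idx)))),
            Block(np.array([p - 1]), None, np.eye(1) * 0.3),
        ]
        codes_g, lev_g = pd.factorize(table["group_id"])
        self.re_factors = [REFactor("group", codes_g.astype(int), len(lev_g), re_prior_scale)]
        self.intercept_indices = np.array([1])  # the count-part intercept

    def loglik_rows(self, theta, re_row, rows=None):
        theta = np.asarray(theta)
        if rows is None:
            X, y, re = self.X, self.y, re_row
        else:
            X, y, re = self.X[rows], self.y[rows], re_row[rows]
        pi = expit(theta[0])
        mu = np.exp(X @ theta[1:-1] + re)
        phi = np.exp(theta[-1])
        return zinb_logpmf(y, pi, mu, phi)


def lrs_fit(table: pd.DataFrame, variant: str = "relative", seed: int = 0,
            scaler: CovariateScaler | None = None, **kw) -> PosteriorDraws:
    """Fit the LRS model; ``variant`` picks relative or absolute covariates."""
    if len(table) < 2:
        raise ValueError("need at least 2 LRS observations")
    model = LRSModel(table, variant, scaler)
    draws = sample_posterior(model, seed=seed, **_kw(kw))
    draws.meta.update({
        "submodel": "lrs", "variant": variant,
        "columns": model.columns,
        "scaler": model.scaler.params,
    })
    return draws


def lrs_expected(params: dict, covariates: dict, scaler: CovariateScaler,
                 columns: list[str]) -> float:
    """Expected LRS (1-pi)*mu at raw-scale covariate values for one draw."""
    eta = params["lrs:intercept"]
    for c in columns:
        eta += params[f"lrs:{c}"] * float(scaler.transform_values(c, [covariates[c]])[0])
    return float((1.0 - expit(params["lrs:zero_logit"])) * np.exp(eta))
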