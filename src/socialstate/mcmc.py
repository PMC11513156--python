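"""Adaptive Metropolis-within-Gibbs sampler for hierarchical regression models.

The sampler targets posteriors of the form

    p(theta, u, sigma | y)  ∝  L(y | theta, u) · N(theta; m0, S0)
                               · prod_f N(u_f; 0, sigma_f) · halfN(sigma_f; s_f)

where ``theta`` collects fixed effects (and transformed auxiliary scalars such
as a log residual SD), and ``u_f`` are crossed random-effect vectors (e.g.
oestrus event, group and male identity).  Updates:

* fixed effects in blocks via random-walk Metropolis, preconditioned with a
  model-supplied Cholesky factor (typically of ``(X'X/n)^-1``) and a scalar
  step size adapted during burn-in towards standard acceptance targets;
* each random-effect factor as a vectorized set of independent per-level
  Metropolis updates (levels of one factor are conditionally independent
  given everything else);
* random-effect SDs via random-walk Metropolis on the log scale (their
  conditional involves only the effect values and the half-Normal prior).

Correctness is enforced by quadrature and parameter-recovery tests rather
than by matching any particular reference sampler's output stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


# ---------------------------------------------------------------------------
# Convergence diagnostic
# ---------------------------------------------------------------------------

def rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, n) or (chains, n, params).  Each chain is
    split in half, the between- and within-chain variances are pooled, and
    R-hat = sqrt(((n-1)/n · W + B/n) / W).  Values near 1 indicate that the
    chains have mixed over the same distribution.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
        squeeze = True
    else:
        squeeze = False
    m, n, p = x.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 10:
        raise ValueError("R-hat requires at least 10 retained draws per chain")
    half = n // 2
    split = np.concatenate([x[:, :half, :], x[:, half: 2 * half, :]], axis=0)
    m2, n2, _ = split.shape
    chain_means = split.mean(axis=1)                      # (m2, p)
    within = split.var(axis=1, ddof=1).mean(axis=0)       # (p,)
    between = n2 * chain_means.var(axis=0, ddof=1)        # (p,)
    var_plus = (n2 - 1) / n2 * within + between / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / within)
    return float(out[0]) if squeeze else out


# ---------------------------------------------------------------------------
# Model interface
# ---------------------------------------------------------------------------

@dataclass
class Block:
    """A block of fixed-effect parameters updated jointly.

    ``rows`` restricts the likelihood evaluation to the observations the
    block's parameters touch (None = all rows); ``prop_chol`` is the
    Cholesky preconditioner of the proposal covariance.
    """

    indices: np.ndarray
    rows: np.ndarray | None
    prop_chol: np.ndarray


@dataclass
class REFactor:
    """A crossed random-effect factor (zero-mean Gaussian, scalar per level)."""

    name: str
    codes: np.ndarray          # per-row level index
    n_levels: int
    prior_scale: float = 1.0   # half-Normal prior scale for the SD


class HierarchicalModel:
    """Interface the sampler expects; concrete models fill these in.

    ``intercept_indices`` lists the theta entries that trade off one-for-one
    against a constant shift of every random-effect field (used by the
    interweaving translation move that decorrelates intercepts from
    random-effect locations).
    """

    theta_names: list[str]
    prior_mean: np.ndarray
    prior_sd: np.ndarray
    blocks: list[Block]
    re_factors: list[REFactor]
    n_rows: int
    intercept_indices: np.ndarray = np.empty(0, dtype=int)

    def loglik_rows(self, theta, re_row, rows=None) -> np.ndarray:
        raise NotImplementedError

    def init_theta(self, rng) -> np.ndarray:
        return np.zeros(len(self.theta_names))


def design_preconditioner(X: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Cholesky factor of (X'X/n + ridge·I)^-1, a cheap curvature proxy."""
    n = max(len(X), 1)
    A = X.T @ X / n + ridge * np.eye(X.shape[1])
    return np.linalg.cholesky(np.linalg.inv(A))


# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Labelled posterior draws across chains with per-parameter diagnostics."""

    names: list[str]
    draws: np.ndarray                 # (chains, n_draws, n_params)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rhat = rhat(self.draws)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def param(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains flattened."""
        j = self.names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def rhat_of(self, name: str) -> float:
        return float(self._rhat[self.names.index(name)])

    def rhat_all(self) -> dict:
        return dict(zip(self.names, self._rhat))

    def summary(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "parameter": self.names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "lo_2.5": lo,
            "hi_97.5": hi,
            "rhat": self._rhat,
        })

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.param(name)
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(x, [a, 100 - a])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        m, n, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(m * n, p), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(m), n))
        df.insert(1, "draw", np.tile(np.arange(n), m))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "PosteriorDraws":
        names = [c for c in df.columns if c not in ("chain", "draw")]
        chains = sorted(df["chain"].unique())
        arr = np.stack([
            df[df["chain"] == c].sort_values("draw")[names].to_numpy() for c in chains
        ])
        return cls(names, arr, meta or {})


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

_INIT_RETRIES = 20


def _halfnorm_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(_norm_logpdf(x, 0.0, scale) + np.log(2.0))


def sample_posterior(
    model: HierarchicalModel,
    chains: int = 3,
    iterations: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 100,
    seed: int = 0,
) -> PosteriorDraws:
    """Draw from the posterior of a hierarchical model.

    Defaults mirror the chain settings used for the reproductive-state
    transition models (3 chains, 20 000 iterations, burn-in 2000, thinning
    100); callers scale these down for quick runs.  Output is reproducible
    for a fixed (seed, chains).
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for convergence checks")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if thin < 1:
        raise ValueError("thinning interval must be >= 1")

    ss = np.random.SeedSequence(seed)
    per_chain = []
    for child in ss.spawn(chains):
        per_chain.append(_run_chain(model, iterations, burn_in, thin, np.random.default_rng(child)))
    names = list(model.theta_names) + [f"sd_{f.name}" for f in model.re_factors]
    draws = np.stack(per_chain)
    if not np.all(np.isfinite(draws)):
        raise RuntimeError("non-finite posterior draws after burn-in")
    return PosteriorDraws(names, draws, {"iterations": iterations, "burn_in": burn_in,
                                         "thin": thin, "chains": chains, "seed": seed})


def _run_chain(model, iterations, burn_in, thin, rng):
    n_theta = len(model.theta_names)
    factors = model.re_factors

    # --- initialization with retries on non-finite likelihood
    for attempt in range(_INIT_RETRIES):
        theta = model.init_theta(rng) + (0.1 * attempt) * rng.standard_normal(n_theta)
        u = {f.name: np.zeros(f.n_levels) for f in factors}
        re_row = _re_row(model, u, factors)
        ll_rows = model.loglik_rows(theta, re_row)
        if np.all(np.isfinite(ll_rows)):
            break
    else:
        raise RuntimeError(
            "could not initialize chain: likelihood non-finite after "
            f"{_INIT_RETRIES} attempts (check the design table for degeneracies)"
        )

    sd = {f.name: 0.5 for f in factors}
    log_step_block = np.zeros(len(model.blocks))
    log_step_factor = {f.name: np.log(0.5) for f in factors}
    log_step_sd = {f.name: np.log(0.5) for f in factors}
    log_step_tr = np.full(len(factors), np.log(0.3))
    log_step_rescale = np.full(len(factors), np.log(0.3))

    kept = []
    for t in range(1, iterations + 1):
        adapt = t <= burn_in
        gamma = (t + 10) ** -0.6

        # ---- fixed-effect blocks
        for bi, block in enumerate(model.blocks):
            idx = block.indices
            d = len(idx)
            prop = theta.copy()
            prop[idx] = theta[idx] + np.exp(log_step_block[bi]) * (
                block.prop_chol @ rng.standard_normal(d)
            )
            rows = block.rows
            if rows is None:
                ll_old = ll_rows.sum()
                ll_new_rows = model.loglik_rows(prop, re_row)
                ll_new = ll_new_rows.sum()
            else:
                ll_old = ll_rows[rows].sum()
                ll_new_rows = model.loglik_rows(prop, re_row, rows)
                ll_new = ll_new_rows.sum()
            lp = (
                _norm_logpdf(prop[idx], model.prior_mean[idx], model.prior_sd[idx]).sum()
                - _norm_logpdf(theta[idx], model.prior_mean[idx], model.prior_sd[idx]).sum()
            )
            log_alpha = ll_new - ll_old + lp
            acc = np.log(rng.uniform()) < log_alpha if np.isfinite(log_alpha) else False
            if acc:
                theta = prop
                if rows is None:
                    ll_rows = ll_new_rows
                else:
                    ll_rows = ll_rows.copy()
                    ll_rows[rows] = ll_new_rows
            if adapt:
                target = 0.234 if d > 2 else 0.40
                log_step_block[bi] += gamma * ((1.0 if acc else 0.0) - target)

        # ---- random-effect levels (vectorized independent per-level updates)
        for f in factors:
            if sd[f.name] == 0.0:
                continue
            step = np.exp(log_step_factor[f.name])
            u_old = u[f.name]
            u_new = u_old + step * rng.standard_normal(f.n_levels)
            re_new = re_row + (u_new - u_old)[f.codes]
            ll_new_rows = model.loglik_rows(theta, re_new)
            ll_by_level_old = np.bincount(f.codes, weights=ll_rows, minlength=f.n_levels)
            ll_by_level_new = np.bincount(f.codes, weights=ll_new_rows, minlength=f.n_levels)
            lp = _norm_logpdf(u_new, 0.0, sd[f.name]) - _norm_logpdf(u_old, 0.0, sd[f.name])
            log_alpha = ll_by_level_new - ll_by_level_old + lp
            accept = np.log(rng.uniform(size=f.n_levels)) < log_alpha
            if accept.any():
                u[f.name] = np.where(accept, u_new, u_old)
                row_mask = accept[f.codes]
                re_row = np.where(row_mask, re_new, re_row)
                ll_rows = np.where(row_mask, ll_new_rows, ll_rows)
            if adapt:
                log_step_factor[f.name] += gamma * (accept.mean() - 0.44)

        # ---- interweaving translation moves: shift intercepts against one
        # random-effect field; the likelihood is invariant, so only priors
        # enter the ratio.  Decorrelates intercepts from RE locations.
        ii = model.intercept_indices
        if len(ii):
            for fi, f in enumerate(factors):
                delta = np.exp(log_step_tr[fi]) * rng.standard_normal()
                th_new = theta[ii] + delta
                u_new = u[f.name] - delta
                lp = (
                    _norm_logpdf(th_new, model.prior_mean[ii], model.prior_sd[ii]).sum()
                    - _norm_logpdf(theta[ii], model.prior_mean[ii], model.prior_sd[ii]).sum()
                    + _norm_logpdf(u_new, 0.0, sd[f.name]).sum()
                    - _norm_logpdf(u[f.name], 0.0, sd[f.name]).sum()
                )
                acc = np.log(rng.uniform()) < lp
                if acc:
                    theta = theta.copy()
                    theta[ii] = th_new
                    u[f.name] = u_new
                    re_row = re_row - delta
                    # net linear predictor is unchanged, so ll_rows stands
                if adapt:
                    log_step_tr[fi] += gamma * ((1.0 if acc else 0.0) - 0.40)

        # ---- rescaling moves: scale one RE field and its SD together.
        # Under (sd, u) -> (sd e^d, u e^d) the Gaussian prior term cancels
        # against the Jacobian up to e^d, so the ratio is the likelihood
        # change times the half-Normal prior ratio times e^d.  Lets the SD
        # escape near-zero traps by dragging the whole field with it.
        # Run every third sweep: it needs full likelihood evaluations and
        # only has to move the SD occasionally.
        for fi, f in (enumerate(factors) if t % 3 == 0 else ()):
            d_scale = np.exp(log_step_rescale[fi]) * rng.standard_normal()
            factor_scale = np.exp(d_scale)
            u_new = u[f.name] * factor_scale
            sd_new = sd[f.name] * factor_scale
            re_new = re_row + (u_new - u[f.name])[f.codes]
            ll_new_rows = model.loglik_rows(theta, re_new)
            log_alpha = (
                ll_new_rows.sum() - ll_rows.sum()
                + _halfnorm_logpdf(sd_new, f.prior_scale)
                - _halfnorm_logpdf(sd[f.name], f.prior_scale)
                + d_scale
            )
            acc = np.log(rng.uniform()) < log_alpha if np.isfinite(log_alpha) else False
            if acc:
                u[f.name] = u_new
                sd[f.name] = sd_new
                re_row = re_new
                ll_rows = ll_new_rows
            if adapt:
                log_step_rescale[fi] += gamma * ((1.0 if acc else 0.0) - 0.40)

        # ---- random-effect SDs (conditional on effect values only)
        for f in factors:
            cur = sd[f.name]
            prop_sd = cur * np.exp(np.exp(log_step_sd[f.name]) * rng.standard_normal())
            uu = u[f.name]
            lp_new = (
                _norm_logpdf(uu, 0.0, prop_sd).sum()
                + _halfnorm_logpdf(prop_sd, f.prior_scale) + np.log(prop_sd)
            )
            lp_old = (
                _norm_logpdf(uu, 0.0, cur).sum()
                + _halfnorm_logpdf(cur, f.prior_scale) + np.log(cur)
            )
            acc = np.log(rng.uniform()) < lp_new - lp_old
            if acc:
                sd[f.name] = prop_sd
            if adapt:
                log_step_sd[f.name] += gamma * ((1.0 if acc else 0.0) - 0.40)

        if t > burn_in and (t - burn_in) % thin == 0:
            kept.append(np.concatenate([theta, [sd[f.name] for f in factors]]))

    return np.asarray(kept)


def _re_row(model, u, factors):
    re_row = np.zeros(model.n_rows)
    for f in factors:
        re_row = re_row + u[f.name][f.codes]
    return re_row
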