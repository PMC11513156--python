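"""Posterior-predictive surfaces and raw-data summaries.

Simulates plotted probabilities from posterior draws: transition-probability
curves against covariates (population level, random effects at zero,
non-focal covariates held at reference values), expected-value curves for the
fitness models, the quadratic-age switch point of guarding activity, and the
raw mortality contingency table by state and weight class.
"""

from __future__ import annotations

import pathlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import DEAD, GUARD, STATE_NAMES, SUBORDINATE
from .mcmc import PosteriorDraws
from .multistate_model import transition_matrix_at
from .preprocessing import CovariateScaler


@dataclass
class PredictionCurve:
    """Posterior mean and equal-tailed 95% band over a covariate grid."""

    covariate: str
    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.covariate: self.grid,
            "mean": self.mean, "lo_2.5": self.lo, "hi_97.5": self.hi,
        })


def _param_dicts(draws: PosteriorDraws) -> list[dict]:
    flat = draws.draws.reshape(-1, draws.draws.shape[2])
    return [dict(zip(draws.names, row)) for row in flat]


def _warn_if_unconverged(draws: PosteriorDraws, names, threshold: float = 1.1) -> None:
    bad = [n for n in names if n in draws.names and draws.rhat_of(n) >= threshold]
    if bad:
        warnings.warn(f"parameters not converged (R-hat >= {threshold}): {bad}")


def transition_curve(
    trans_draws: PosteriorDraws,
    mort_draws: PosteriorDraws | None,
    origin: int,
    destination: int,
    covariate: str,
    grid,
    reference: dict,
    scaler: CovariateScaler,
    variant: str,
    support: tuple | None = None,
) -> PredictionCurve:
    """Posterior curve of P(origin -> destination) against one covariate.

    With mortality draws supplied the curve is the unconditional probability
    (mortality composed with the live-destination multinomial, paired draw by
    draw); without them it is conditional on survival.  Non-focal covariates
    sit at the ``reference`` values (raw scale); random effects are zero.
    """
    grid = np.asarray(grid, dtype=float)
    if support is not None and (grid.min() < support[0] or grid.max() > support[1]):
        warnings.warn(f"grid for {covariate} extrapolates beyond observed support {support}")
    tdicts = _param_dicts(trans_draws)
    _warn_if_unconverged(trans_draws, trans_draws.names)
    if mort_draws is not None:
        mdicts = _param_dicts(mort_draws)
        _warn_if_unconverged(mort_draws, mort_draws.names)
        n = min(len(tdicts), len(mdicts))
    else:
        mdicts = None
        n = len(tdicts)

    zero_mort = {f"mort:{STATE_NAMES[s]}:intercept": -np.inf for s in (0, 1, 2)} | {
        f"mort:{STATE_NAMES[s]}:group_centred_weight": 0.0 for s in (0, 1, 2)
    }
    vals = np.empty((n, len(grid)))
    for i in range(n):
        tp = tdicts[i]
        mp = mdicts[i] if mdicts is not None else zero_mort
        for j, g in enumerate(grid):
            cov = dict(reference)
            cov[covariate] = g
            mat = transition_matrix_at(tp, mp, cov, scaler, variant)
            vals[i, j] = mat[origin, destination]
    lo, hi = np.percentile(vals, [2.5, 97.5], axis=0)
    return PredictionCurve(
        covariate, grid, vals.mean(axis=0), lo, hi,
        label=f"{STATE_NAMES[origin]}>{STATE_NAMES[destination]}",
    )


def posterior_curve(
    draws: PosteriorDraws,
    fn,
    covariate: str,
    grid,
    reference: dict,
    label: str = "",
) -> PredictionCurve:
    """Generic per-draw curve: ``fn(param_dict, covariates) -> value``."""
    grid = np.asarray(grid, dtype=float)
    dicts = _param_dicts(draws)
    vals = np.empty((len(dicts), len(grid)))
    for i, p in enumerate(dicts):
        for j, g in enumerate(grid):
            cov = dict(reference)
            cov[covariate] = g
            vals[i, j] = fn(p, cov)
    lo, hi = np.percentile(vals, [2.5, 97.5], axis=0)
    return PredictionCurve(covariate, grid, vals.mean(axis=0), lo, hi, label=label)


# ---------------------------------------------------------------------------
# Raw mortality contingency table
# ---------------------------------------------------------------------------

def summarize_raw_mortality(transitions: pd.DataFrame) -> pd.DataFrame:
    """Deaths by origin state and weight class straight from the raw intervals.

    Classifies guard and subordinate intervals by the sign of group-centred
    weight (strictly below 0 = "below average"; 0 counts as "average and
    above"), counts death outcomes and computes percentages rounded to one
    decimal place.  Sneaker intervals go to a remainder bucket; empty cells
    report a missing percentage rather than 0.
    """
    if transitions["group_centred_weight"].isna().any():
        raise ValueError("group-centred weight must be present on every row")
    rows = []
    for state in (GUARD, SUBORDINATE):
        for label, mask_w in (
            ("below_average", transitions["group_centred_weight"] < 0),
            ("average_and_above", transitions["group_centred_weight"] >= 0),
        ):
            sub = transitions[(transitions["origin_state"] == state) & mask_w]
            deaths = int((sub["outcome"] == DEAD).sum())
            total = int(len(sub))
            rows.append({
                "state": STATE_NAMES[state],
                "weight_class": label,
                "deaths": deaths,
                "totals": total,
                "percent": round(100.0 * deaths / total, 1) if total else np.nan,
            })
    sneak = transitions[~transitions["origin_state"].isin([GUARD, SUBORDINATE])]
    rows.append({
        "state": "sneaker_excluded",
        "weight_class": "all",
        "deaths": int((sneak["outcome"] == DEAD).sum()),
        "totals": int(len(sneak)),
        "percent": np.nan,
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quadratic switch point
# ---------------------------------------------------------------------------

def quadratic_switch_point(
    draws: PosteriorDraws,
    scaler: CovariateScaler,
    linear_name: str = "subordinate>guard:age_years",
    quadratic_name: str = "subordinate>guard:age_sq",
) -> dict:
    """Posterior of the age at which guarding probability peaks.

    Back-transforms the standardized linear and quadratic age coefficients to
    the raw scale and evaluates -b1/(2 b2) per draw.  Draws with exactly zero
    curvature are skipped (and counted); if the curvature is not
    predominantly negative the curve has no interior maximum and a warning is
    raised.
    """
    b1_std = draws.param(linear_name)
    b2_std = draws.param(quadratic_name)
    s1 = scaler.params["age_years"]["scale"]
    s2 = scaler.params["age_sq"]["scale"]
    b1 = b1_std / s1
    b2 = b2_std / s2
    keep = b2 != 0.0
    n_skipped = int((~keep).sum())
    frac_neg = float((b2 < 0).mean())
    if frac_neg < 0.5:
        warnings.warn(
            "quadratic age curvature is not predominantly negative: "
            "no interior guarding peak; switch point reported at boundary"
        )
    sp = -b1[keep] / (2.0 * b2[keep])
    lo, hi = np.percentile(sp, [2.5, 97.5])
    return {
        "mean": float(sp.mean()),
        "median": float(np.median(sp)),
        "ci": (float(lo), float(hi)),
        "n_skipped": n_skipped,
        "frac_negative_curvature": frac_neg,
    }


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(
    outdir,
    curves: dict[str, PredictionCurve],
    raw_mortality: pd.DataFrame | None = None,
    summaries: dict[str, pd.DataFrame] | None = None,
    extras: dict | None = None,
    make_figures: bool = True,
) -> pathlib.Path:
    """Write a human-readable markdown report plus CSV tables and figures.

    Deterministic given its inputs: tables re-rendered from the same curves
    and summaries are byte-identical.
    """
    if not curves and not summaries:
        raise ValueError(
            "nothing to report: supply at least one fitted model's curves or summaries"
        )
    outdir = pathlib.Path(outdir)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)

    lines = ["# Reproductive life-history model report", ""]
    for name, curve in curves.items():
        path = outdir / "curves" / f"{name}.csv"
        curve.to_frame().to_csv(path, index=False, float_format="%.6g")
        lines.append(f"- curve `{name}` ({curve.label or curve.covariate}): `curves/{name}.csv`")
    if raw_mortality is not None:
        raw_mortality.to_csv(outdir / "raw_mortality.csv", index=False)
        lines += ["", "## Raw mortality by state and weight class", ""]
        lines.append(raw_mortality.to_string(index=False))
    if summaries:
        lines += ["", "## Posterior summaries", ""]
        for name, df in summaries.items():
            df.to_csv(outdir / f"summary_{name}.csv", index=False, float_format="%.6g")
            lines.append(f"### {name}")
            lines.append(df.to_string(index=False))
            lines.append("")
    if extras:
        lines += ["", "## Derived quantities", ""]
        for k, v in extras.items():
            lines.append(f"- {k}: {v}")

    if make_figures and curves:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, curve in curves.items():
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.fill_between(curve.grid, curve.lo, curve.hi, alpha=0.3, color="grey")
            ax.plot(curve.grid, curve.mean, color="black")
            ax.set_xlabel(curve.covariate)
            ax.set_ylabel(curve.label or "value")
            fig.tight_layout()
            fig.savefig(outdir / "curves" / f"{name}.png", dpi=100)
            plt.close(fig)

    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
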