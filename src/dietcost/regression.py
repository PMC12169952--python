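"""Diet cost vs. diet-quality score: spline regression and percentile contrasts.

The association between usual daily diet cost and a dietary-index score is
modelled by weighted least squares on a restricted cubic spline (RCS)
basis of the score, optionally adjusting for usual energy intake.  The
effect size is reported as the fitted cost difference between the 75th
and 25th weighted percentiles of the score distribution, with standard
errors and 95 % confidence intervals from a participant-level bootstrap.

The RCS basis is the standard natural-spline construction: ``k`` knots
yield ``k - 1`` regressors (the linear term plus ``k - 2`` cubic terms),
with the fitted curve exactly linear beyond the boundary knots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SplineConfig",
    "SplineContrast",
    "rcs_basis",
    "weighted_quantile",
    "fit_cost_model",
    "percentile_contrast",
    "bootstrap_contrast",
    "subgroup_contrasts",
]

logger = logging.getLogger(__name__)


@dataclass
class SplineConfig:
    """Spline and contrast settings for one score variable."""

    knot_percentiles: tuple = (5, 35, 65, 95)
    linear_only: bool = False  # plain linear model (low-variation scores)
    energy_adjust: bool = True
    p_hi: float = 75.0
    p_lo: float = 25.0
    n_boot: int = 200
    seed: int = 0
    min_iqr: float = 1e-6  # below this the score is degenerate; skip

    def __post_init__(self) -> None:
        kp = tuple(self.knot_percentiles)
        if not self.linear_only:
            if len(kp) < 3:
                raise ValueError("restricted cubic splines need >= 3 knots")
            if any(not 0 < p < 100 for p in kp) or any(
                kp[i] >= kp[i + 1] for i in range(len(kp) - 1)
            ):
                raise ValueError("knot percentiles must be strictly increasing in (0,100)")


@dataclass
class SplineContrast:
    """Fitted cost difference between two score percentiles."""

    score_variable: str
    delta_cost: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    se: float = np.nan
    n_boot: int = 0
    energy_adjusted: bool = False
    p_hi: float = 75.0
    p_lo: float = 25.0
    x_hi: float = np.nan
    x_lo: float = np.nan
    n: int = 0
    skipped: str | None = None


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear tails).

    With knots ``t_1 < ... < t_k`` the basis has ``k - 1`` columns: the
    linear term and, for ``j = 1..k-2``,

        C_j(x) = [ (x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

    The normalization by the squared knot range keeps the columns on the
    scale of ``x``.  The function is exactly linear outside [t_1, t_k].
    """
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if len(np.unique(t)) != k:
        raise ValueError("knots must be distinct")
    cols = [x]
    norm = (t[-1] - t[0]) ** 2
    for j in range(k - 2):
        term = (
            np.maximum(x - t[j], 0.0) ** 3
            - np.maximum(x - t[-2], 0.0) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.maximum(x - t[-1], 0.0) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def weighted_quantile(x, q, weights=None) -> np.ndarray:
    """Weighted quantiles with type-7-style linear interpolation.

    Sorts ``x``, forms the normalized cumulative weight positions
    ``(F_i - w_i/2) / W`` and interpolates; with equal weights and large n
    this matches the usual interpolated sample quantile.
    """
    x = np.asarray(x, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float)) / 100.0
    if weights is None:
        weights = np.ones_like(x)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= np.sum(ws)
    out = np.interp(q, cum, xs)
    return out if out.size > 1 else float(out[0])


def _design(score, energy, weights, config: SplineConfig):
    """Design matrix, knots, and column names for the cost model."""
    score = np.asarray(score, dtype=float)
    knots = None
    if not config.linear_only:
        knots = np.unique(
            [weighted_quantile(score, p, weights) for p in config.knot_percentiles]
        )
        if len(knots) < len(config.knot_percentiles):
            logger.info(
                "score mass concentrated at knot positions; %d unique knots left",
                len(knots),
            )
        if len(knots) < 3:
            knots = None  # too little variation for a spline; linear fallback
    if knots is None:
        basis = score[:, None]
        names = ["score"]
    else:
        basis = rcs_basis(score, knots)
        names = ["score"] + [f"score_rcs{j}" for j in range(1, basis.shape[1])]
    cols = [np.ones_like(score), *basis.T]
    names = ["const"] + names
    if config.energy_adjust:
        cols.append(np.asarray(energy, dtype=float))
        names.append("energy")
    X = np.column_stack(cols)
    return X, knots, names


def fit_cost_model(cost, score, energy, weights, config: SplineConfig):
    """Weighted least squares of usual cost on RCS(score) [+ usual energy].

    Returns (fitted statsmodels results, knots, column names).
    """
    X, knots, names = _design(score, energy, weights, config)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); columns: {names}"
        )
    model = sm.WLS(np.asarray(cost, dtype=float), X, weights=np.asarray(weights, dtype=float))
    return model.fit(), knots, names


def percentile_contrast(
    fit_result,
    knots,
    names,
    score,
    weights,
    config: SplineConfig,
    energy=None,
) -> tuple[float, float, float]:
    """Fitted cost difference between two score percentiles.

    Percentiles are computed on the weighted pooled score distribution;
    other covariates (energy) are held at their weighted means, so they
    cancel in the difference.  Returns (delta, x_lo, x_hi).
    """
    score = np.asarray(score, dtype=float)
    x_lo = weighted_quantile(score, config.p_lo, weights)
    x_hi = weighted_quantile(score, config.p_hi, weights)
    pts = np.array([x_lo, x_hi])
    if config.linear_only or knots is None:
        basis = pts[:, None]
    else:
        basis = rcs_basis(pts, knots)
    cols = [np.ones(2), *basis.T]
    if config.energy_adjust:
        w = np.asarray(weights, dtype=float)
        ebar = float(np.sum(w * np.asarray(energy, dtype=float)) / np.sum(w))
        cols.append(np.full(2, ebar))
    X = np.column_stack(cols)
    pred = X @ fit_result.params
    return float(pred[1] - pred[0]), float(x_lo), float(x_hi)


def _contrast_once(df: pd.DataFrame, score_var: str, config: SplineConfig) -> tuple:
    w = df["weight"].to_numpy()
    fit, knots, names = fit_cost_model(
        df["cost"].to_numpy(), df[score_var].to_numpy(), df["energy"].to_numpy(), w, config
    )
    delta, x_lo, x_hi = percentile_contrast(
        fit, knots, names, df[score_var].to_numpy(), w, config, df["energy"].to_numpy()
    )
    return delta, x_lo, x_hi


def bootstrap_contrast(
    data: pd.DataFrame,
    score_var: str,
    config: SplineConfig,
    ci_method: str = "normal",
) -> SplineContrast:
    """Point estimate and bootstrap CI of the P_hi - P_lo cost contrast.

    ``data`` is a pooled (pseudo-)population frame with columns
    ``participant_id, cost, energy, weight`` and the score variable.
    Participants are resampled with replacement -- pseudo-individuals
    travel with their participant, since they are not independent
    observations.  The CI is a normal approximation from the bootstrap SE
    (percentile CI available via ``ci_method="percentile"``).

    A score with zero interquartile range cannot support a contrast; the
    result is returned with ``skipped`` set instead of raising.
    """
    w = data["weight"].to_numpy()
    score = data[score_var].to_numpy()
    iqr = weighted_quantile(score, config.p_hi, w) - weighted_quantile(score, config.p_lo, w)
    n_participants = data["participant_id"].nunique()
    if abs(iqr) <= config.min_iqr:
        logger.info("skipping %s: degenerate score distribution (IQR=%.3g)", score_var, iqr)
        return SplineContrast(
            score_variable=score_var,
            delta_cost=np.nan,
            energy_adjusted=config.energy_adjust,
            p_hi=config.p_hi,
            p_lo=config.p_lo,
            n=n_participants,
            skipped="degenerate score distribution (near-zero IQR)",
        )
    delta, x_lo, x_hi = _contrast_once(data, score_var, config)

    rng = np.random.default_rng(config.seed)
    uniq = data["participant_id"].unique()
    groups = {pid: idx.to_numpy() for pid, idx in data.groupby("participant_id").groups.items()}
    boots = []
    for _ in range(config.n_boot):
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([groups[p] for p in pick])
        try:
            boots.append(_contrast_once(data.loc[idx], score_var, config))
        except ValueError:
            continue  # degenerate resample (e.g. duplicate knots); drop it
    deltas = np.array([b[0] for b in boots])
    if len(deltas) > 1:
        se = float(np.std(deltas, ddof=1))
        if ci_method == "percentile":
            lo, hi = np.percentile(deltas, [2.5, 97.5])
        else:
            lo, hi = delta - 1.96 * se, delta + 1.96 * se
    else:
        se, lo, hi = 0.0, delta, delta
    return SplineContrast(
        score_variable=score_var,
        delta_cost=delta,
        ci_low=float(min(lo, delta)),
        ci_high=float(max(hi, delta)),
        se=se,
        n_boot=len(deltas),
        energy_adjusted=config.energy_adjust,
        p_hi=config.p_hi,
        p_lo=config.p_lo,
        x_lo=x_lo,
        x_hi=x_hi,
        n=n_participants,
    )


def subgroup_contrasts(
    data: pd.DataFrame,
    score_var: str,
    config: SplineConfig,
    cohort: pd.DataFrame,
    groupings: tuple = ("sex", "age_group", "education", "income", "smoking", "region"),
) -> pd.DataFrame:
    """Re-run the full contrast within each sociodemographic subgroup.

    Score percentiles (and knots) are recomputed within each subgroup.
    Returns one row per (grouping, level) with the contrast and CI.
    """
    meta = cohort.set_index("participant_id")
    rows = []
    for gvar in groupings:
        levels = meta[gvar].dropna().unique()
        for level in sorted(levels):
            pids = meta.index[meta[gvar] == level]
            sub = data[data["participant_id"].isin(pids)]
            if sub.empty:
                continue
            res = bootstrap_contrast(sub.reset_index(drop=True), score_var, config)
            rows.append(
                {
                    "grouping": gvar,
                    "level": level,
                    "n": res.n,
                    "delta_cost": res.delta_cost,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "se": res.se,
                    "skipped": res.skipped,
                }
            )
    return pd.DataFrame(rows)
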