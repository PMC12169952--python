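"""Usual-intake estimation from replicate 24-h recalls.

Single-day recalls measure a person's *usual* (long-run average) intake
with large day-to-day error, and episodically consumed foods produce many
true zeros.  This module fits a multivariate two-part nonlinear mixed
model in the spirit of the National Cancer Institute's multivariate
method and simulates "pseudo-individuals" -- Monte Carlo draws of each
participant's plausible usual intake vector -- so that downstream
analyses (index scoring, cost regression) operate on usual rather than
single-day quantities.

Model (per sex stratum).  For each episodic variable there are two
correlated parts on a latent scale: a probit consumption part and a
Box-Cox-transformed amount part; daily variables (always including
energy and diet cost) have the amount part only.  Writing
``W_id`` for the latent part vector of person ``i`` on day ``d``::

    W_id = X_id' B + u_i + e_id,   u_i ~ MVN(0, S_u),  e_id ~ MVN(0, S_e)

The between-person covariance S_u is unstructured over the amount parts
(this carries the person-level correlations among foods, energy and
cost); probit (consumption-propensity) random effects have free
variances but are kept independent of everything else, because their
covariances are not identifiable from two or three recalls.  The
within-day covariance S_e is unstructured over the daily amount parts
and their covariances with the probit errors (energy and cost really are
lower on a day an episodic food is skipped); probit error variances are
fixed at 1, probit-probit and each food's own probit-amount covariances
at 0, and episodic amount errors are independent -- each of these
entries is either unidentified or driven purely by imputed values.
Covariates are recall-sequence and weekend indicators plus
sociodemographics.

Fitting is by Markov chain Monte Carlo with data augmentation: amount
parts on non-consumption days are imputed from their conditional normal,
person random effects are drawn by a partially collapsed Gibbs step
(probit latents marginalized out, consumption patterns entering through
a Metropolis correction with the exact probit likelihood), and probit
latents are then redrawn from sign-consistent truncated normals.  Weakly
informative inverse-Wishart/inverse-gamma priors sit on the
covariances.

Usual intakes for a pseudo-individual are computed from a posterior draw
of ``u_i`` as ``P(consume) x E[amount | consume]``, back-transforming the
Box-Cox mean with the within-person variance integrated out (Gauss-
Hermite quadrature by default; a second-order Taylor correction is
available).  Sequence indicators are set to their reference (a later
recall) and the weekend indicator to its population share (3/7, Friday
counting as a weekend day).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MEModelSpec",
    "FittedMEModel",
    "classify_episodic",
    "recalls_to_wide",
    "fit",
    "simulate_usual",
    "usual_summaries",
]

logger = logging.getLogger(__name__)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass
class MEModelSpec:
    """Configuration of the measurement-error model."""

    episodic_vars: list[str]
    daily_vars: list[str]  # must include "energy" and "cost"
    covariates: tuple = ("age", "smoking", "income", "education", "region")
    strata: str | None = "sex"
    n_pseudo: int = 500
    n_iter: int = 4000
    n_burn: int = 2000
    thin: int = 4
    seed: int = 0
    boxcox_grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    max_block_foods: int = 10  # larger runs are fitted in correlated blocks
    min_stratum: int = 30
    backtransform: str = "quadrature"  # or "taylor"

    def __post_init__(self) -> None:
        overlap = set(self.episodic_vars) & set(self.daily_vars)
        if overlap:
            raise ValueError(f"variables classified twice: {sorted(overlap)}")
        for v in ("energy", "cost"):
            if v in self.episodic_vars:
                raise ValueError(f"{v} must be a daily variable")
        if self.n_pseudo < 1:
            raise ValueError("n_pseudo must be >= 1")


def classify_episodic(
    recalls: pd.DataFrame,
    weights: pd.Series | None = None,
    threshold: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Split food variables into episodic and daily by first-recall zeros.

    A food is episodic when the (weighted) fraction of participants
    reporting zero intake on their first recall is at or above
    ``threshold`` (inclusive).  Energy and cost are always daily and are
    not part of this classification.
    """
    first = recalls[recalls["recall_index"] == recalls["recall_index"].min()]
    episodic, daily = [], []
    for food, g in first.groupby("food_group", sort=True):
        if weights is None:
            w = np.ones(len(g))
        else:
            w = g["participant_id"].map(weights).to_numpy(dtype=float)
        frac_zero = float(np.sum(w * (g["amount_kg"].to_numpy() == 0)) / np.sum(w))
        (episodic if frac_zero >= threshold else daily).append(food)
    return episodic, daily


def recalls_to_wide(recalls: pd.DataFrame, daily_costs: pd.DataFrame) -> pd.DataFrame:
    """Pivot long recall records to one row per (participant, recall).

    Columns: weekend flag, one amount column per food group, plus the
    daily energy and cost from the costing stage.
    """
    wide = recalls.pivot_table(
        index=["participant_id", "recall_index"],
        columns="food_group",
        values="amount_kg",
        aggfunc="sum",
        fill_value=0.0,
    ).reset_index()
    wide.columns.name = None
    weekend = recalls.groupby(["participant_id", "recall_index"])["weekend"].first()
    wide = wide.merge(weekend.reset_index(), on=["participant_id", "recall_index"])
    wide = wide.merge(
        daily_costs.rename(columns={"energy_kcal": "energy"}),
        on=["participant_id", "recall_index"],
    )
    return wide


# ---------------------------------------------------------------------------
# Box-Cox helpers


def _boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    return np.log(x) if lam == 0 else (np.power(x, lam) - 1.0) / lam


def _select_lambda(x_pos: np.ndarray, grid) -> float:
    """Grid-maximize the Box-Cox log-likelihood on positive amounts."""
    best, best_llf = grid[0], -np.inf
    for lam in grid:
        llf = float(stats.boxcox_llf(lam, x_pos))
        if llf > best_llf:
            best, best_llf = lam, llf
    return float(best)


def _backtransform_mean(m, var, lam: float, method: str = "quadrature") -> np.ndarray:
    """E[g^-1(m + e)] for e ~ N(0, var), g the Box-Cox transform.

    ``m`` and ``var`` broadcast elementwise.  ``quadrature``: 21-node
    Gauss-Hermite, with negative Box-Cox arguments truncated to zero
    intake.  ``taylor``: second-order expansion
    g^-1(m) + var/2 * d2 g^-1/dm^2 (exact for lam=0).
    """
    m = np.asarray(m, dtype=float)
    var = np.maximum(np.broadcast_to(np.asarray(var, dtype=float), m.shape), 0.0)
    if lam == 0:
        return np.exp(m + var / 2.0)
    if method == "taylor":
        base = np.maximum(lam * m + 1.0, 0.0)
        val = np.power(base, 1.0 / lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            second = (1.0 - lam) * np.power(base, 1.0 / lam - 2.0)
        return val + 0.5 * var * np.where(base > 0, second, 0.0)
    pts = m[..., None] + np.sqrt(var)[..., None] * _GH_NODES
    base = np.maximum(lam * pts + 1.0, 0.0)
    return np.power(base, 1.0 / lam) @ _GH_WEIGHTS


# ---------------------------------------------------------------------------
# design matrix


def _build_design(df: pd.DataFrame, cohort: pd.DataFrame, covariates) -> tuple:
    """Day-level fixed-effect design: intercept, first-recall and weekend
    indicators, then person covariates (continuous standardized,
    categoricals dummy-coded dropping the first level)."""
    meta = cohort.set_index("participant_id")
    cols = {"const": np.ones(len(df))}
    cols["first_recall"] = (df["recall_index"] == df["recall_index"].min()).to_numpy(float)
    cols["weekend"] = df["weekend"].to_numpy(dtype=float)
    typical = {"const": 1.0, "first_recall": 0.0, "weekend": 3.0 / 7.0}
    for cv in covariates:
        vals = meta.loc[df["participant_id"], cv]
        if vals.isna().any():
            raise ValueError(f"covariate {cv!r} has missing values; impute first")
        if np.issubdtype(np.asarray(vals).dtype, np.number):
            v = vals.to_numpy(dtype=float)
            mu, sd = float(v.mean()), float(v.std()) or 1.0
            cols[cv] = (v - mu) / sd
            typical[cv] = None  # person-specific, carried through as-is
        else:
            levels = sorted(pd.unique(vals.dropna()))
            for lev in levels[1:]:
                name = f"{cv}[{lev}]"
                cols[name] = (vals == lev).to_numpy(dtype=float)
                typical[name] = None
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    # drop constant / linearly dependent columns (keeps the intercept);
    # an unpivoted QR flags a dependent column by a vanishing diagonal
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    keep = r_diag > 1e-8 * max(r_diag.max(), 1.0)
    keep[0] = True
    if not keep.all():
        dropped = [nm for nm, k in zip(names, keep) if not k]
        logger.info("dropping degenerate design column(s): %s", dropped)
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
    return X, names, typical


# ---------------------------------------------------------------------------
# Gibbs sampler for one block within one stratum


@dataclass
class _BlockFit:
    variables: list[str]  # all modelled variables in order
    episodic: list[str]
    parts: list[tuple[str, str]]  # (variable, "prob"|"amount")
    lambdas: dict
    scale: dict  # var -> (mean, sd) of transformed amounts
    col_names: list[str]
    typical: dict
    participant_ids: np.ndarray
    X_usual: np.ndarray  # per-participant design at the "typical day"
    u_draws: np.ndarray  # (K, n, P)
    beta_draws: np.ndarray  # (K, p, P)
    sigma_e_draws: np.ndarray  # (K, P, P)
    sigma_u_mean: np.ndarray
    sigma_e_mean: np.ndarray
    rhat: dict
    mh_accept: float = np.nan  # mean MH acceptance of the collapsed u-step


def _gibbs_block(
    wide: pd.DataFrame,
    cohort: pd.DataFrame,
    episodic: list[str],
    daily: list[str],
    spec: MEModelSpec,
    rng: np.random.Generator,
) -> _BlockFit:
    variables = list(episodic) + list(daily)
    parts: list[tuple[str, str]] = []
    for v in episodic:
        parts.append((v, "prob"))
    for v in variables:
        parts.append((v, "amount"))
    P = len(parts)
    probit_idx = np.array([k for k, (_, t) in enumerate(parts) if t == "prob"], dtype=int)
    amount_idx = np.array([k for k, (_, t) in enumerate(parts) if t == "amount"], dtype=int)

    wide = wide.sort_values(["participant_id", "recall_index"]).reset_index(drop=True)
    pid = wide["participant_id"].to_numpy()
    uniq_pid, person_of_day = np.unique(pid, return_inverse=True)
    n = len(uniq_pid)
    N = len(wide)
    counts = np.bincount(person_of_day)

    X, col_names, typical = _build_design(wide, cohort, spec.covariates)
    p = X.shape[1]

    # observed data per part
    consumed = {}  # var -> bool (N,)
    W = np.zeros((N, P))
    observed = np.zeros((N, P), dtype=bool)
    lambdas, scale = {}, {}
    for k, (v, part) in enumerate(parts):
        x = wide[v].to_numpy(dtype=float)
        if part == "prob":
            consumed[v] = x > 0
            observed[:, k] = False  # probit latent always augmented
        else:
            if v in episodic:
                mask = x > 0
            else:
                # daily variables may still have occasional zero days;
                # floor them at half the minimum positive value
                mask = np.ones(N, dtype=bool)
                if (x <= 0).any():
                    x = np.where(x > 0, x, x[x > 0].min() / 2.0)
            lam = _select_lambda(x[mask & (x > 0)], spec.boxcox_grid)
            t = np.zeros(N)
            t[mask] = _boxcox(x[mask], lam)
            mu, sd = float(t[mask].mean()), float(t[mask].std())
            sd = sd if sd > 0 else 1.0
            W[mask, k] = (t[mask] - mu) / sd
            observed[:, k] = mask
            lambdas[v] = lam
            scale[v] = (mu, sd)

    # initial values
    beta = np.zeros((p, P))
    XtX = X.T @ X
    XtX_chol = np.linalg.cholesky(XtX + 1e-8 * np.eye(p))
    for k in range(P):
        if observed[:, k].any():
            y0 = np.where(observed[:, k], W[:, k], 0.0)
            beta[:, k] = np.linalg.lstsq(X, y0, rcond=None)[0]
    u = np.zeros((n, P))
    sigma_u = np.eye(P) * 0.3
    sigma_e = np.eye(P) * 0.7
    sigma_e[probit_idx, probit_idx] = 1.0

    nu0 = P + 2
    # between-person prior scale: consumption-propensity (probit) random
    # effects are weakly identified from 2-3 recalls, so their prior leans
    # toward homogeneity; amount-part variances are data-dominated
    S0_u = np.eye(P) * 0.1
    S0_u[probit_idx, probit_idx] = 0.02
    S0_e = np.eye(P) * 0.5

    n_keep = max((spec.n_iter - spec.n_burn) // spec.thin, 1)
    u_draws = np.empty((n_keep, n, P))
    beta_draws = np.empty((n_keep, p, P))
    sigma_e_draws = np.empty((n_keep, P, P))
    sigma_u_sum = np.zeros((P, P))
    sigma_e_sum = np.zeros((P, P))
    diag_u_trace = np.empty((spec.n_iter - spec.n_burn, P))

    # group persons by replicate count for batched u updates
    count_groups = {}
    for c in np.unique(counts):
        count_groups[int(c)] = np.where(counts == c)[0]

    keep = 0
    accept_sum = 0.0
    mh_steps = 0
    # Within-day covariance structure (see module docstring):
    #  * anchored block B = probit parts + daily amount parts: unstructured
    #    except unit probit variances and zero probit-probit covariances --
    #    every entry is identified because both members are observed (or
    #    sign-anchored) on every day.  The probit x daily covariances matter:
    #    energy and cost really are lower on a day an episodic food is
    #    skipped, and without that channel the model would invent spurious
    #    person-level consumption heterogeneity to explain it.
    #  * episodic amount parts: independent within-day errors.  Their
    #    covariances (with anything) are driven by days on which they are
    #    imputed, which sets up a self-reinforcing drift.
    daily_amount_idx = np.array(
        [k for k, (v, t) in enumerate(parts) if t == "amount" and v not in episodic],
        dtype=int,
    )
    episodic_amount_idx = np.array(
        [k for k, (v, t) in enumerate(parts) if t == "amount" and v in episodic],
        dtype=int,
    )
    anchored = np.concatenate([probit_idx, daily_amount_idx])
    anchored.sort()
    probit_in_B = np.searchsorted(anchored, probit_idx)
    daily_in_B = np.searchsorted(anchored, daily_amount_idx)
    nB = len(anchored)
    sigma_B = np.eye(nB)
    sigma_B[np.ix_(daily_in_B, daily_in_B)] = np.eye(len(daily_in_B)) * 0.7
    var_ep = np.full(len(episodic_amount_idx), 0.7)
    a0_ep, b0_ep = 2.0, 0.5
    S0_B = np.eye(nB) * 0.5

    def _assemble_sigma_e():
        s = np.eye(P)
        s[np.ix_(anchored, anchored)] = sigma_B
        s[episodic_amount_idx, episodic_amount_idx] = var_ep
        return s

    for it in range(spec.n_iter):
        mu_fix = X @ beta  # (N, P)
        mean_all = mu_fix + u[person_of_day]
        sigma_e = _assemble_sigma_e()
        lam_e = np.zeros((P, P))
        lam_e[np.ix_(anchored, anchored)] = np.linalg.inv(sigma_B)
        lam_e[episodic_amount_idx, episodic_amount_idx] = 1.0 / var_ep
        # conditionals of each probit error given the daily residuals
        if len(probit_idx) and len(daily_in_B):
            sd_inv = np.linalg.inv(sigma_B[np.ix_(daily_in_B, daily_in_B)])
            c_probit = sigma_B[np.ix_(probit_in_B, daily_in_B)] @ sd_inv  # (nprob, ndaily)
            s_probit = np.sqrt(
                1.0
                - np.einsum(
                    "kj,kj->k",
                    c_probit,
                    sigma_B[np.ix_(probit_in_B, daily_in_B)],
                )
            )
        else:
            sd_inv = None
            c_probit = np.zeros((len(probit_idx), len(daily_in_B)))
            s_probit = np.ones(len(probit_idx))

        # --- impute latent amounts on non-consumption days
        resid = W - mean_all
        for k in amount_idx:
            miss = ~observed[:, k]
            if not miss.any():
                continue
            v_k = 1.0 / lam_e[k, k]
            # conditional mean of e_k given the other residuals
            adj = resid @ lam_e[:, k] - resid[:, k] * lam_e[k, k]
            cond_mean = mean_all[:, k] - v_k * adj
            W[miss, k] = cond_mean[miss] + np.sqrt(v_k) * rng.standard_normal(miss.sum())
            resid[miss, k] = W[miss, k] - mean_all[miss, k]

        # --- person random effects, partially collapsed over the probit
        # latents: the Gaussian proposal is the exact full conditional of u
        # given the amount parts (probit latents marginalized out), and the
        # consumption patterns enter through a Metropolis accept step using
        # the exact probit likelihood conditional on the daily residuals.
        # (A plain latent-then-u cycle has no anchor for persons whose
        # recalls are all-consumption or all-zero and lets the probit
        # random-effect scale drift.)
        lam_pad = np.zeros((P, P))
        if len(daily_amount_idx):
            lam_pad[np.ix_(daily_amount_idx, daily_amount_idx)] = sd_inv if sd_inv is not None else np.linalg.inv(
                sigma_B[np.ix_(daily_in_B, daily_in_B)]
            )
        lam_pad[episodic_amount_idx, episodic_amount_idx] = 1.0 / var_ep
        E = W - mu_fix
        E[:, probit_idx] = 0.0
        sums = np.zeros((n, P))
        np.add.at(sums, person_of_day, E)
        sigma_u_inv = np.linalg.inv(sigma_u)
        u_prop = np.empty_like(u)
        for c, idx in count_groups.items():
            cov = np.linalg.inv(sigma_u_inv + c * lam_pad)
            chol = np.linalg.cholesky(cov)
            means = sums[idx] @ (lam_pad @ cov)
            u_prop[idx] = means + rng.standard_normal((len(idx), P)) @ chol.T
        if len(probit_idx):
            delta = np.zeros(n)
            if len(daily_amount_idx):
                Ed = W[:, daily_amount_idx] - mu_fix[:, daily_amount_idx]
                ed_new = Ed - u_prop[person_of_day][:, daily_amount_idx]
                ed_old = Ed - u[person_of_day][:, daily_amount_idx]
            for j, k in enumerate(probit_idx):
                c = consumed[parts[k][0]]
                if len(daily_amount_idx):
                    shift_new = ed_new @ c_probit[j]
                    shift_old = ed_old @ c_probit[j]
                else:
                    shift_new = shift_old = 0.0
                eta_new = (mu_fix[:, k] + u_prop[person_of_day, k] + shift_new) / s_probit[j]
                eta_old = (mu_fix[:, k] + u[person_of_day, k] + shift_old) / s_probit[j]
                ll = np.where(c, special.log_ndtr(eta_new), special.log_ndtr(-eta_new))
                ll -= np.where(c, special.log_ndtr(eta_old), special.log_ndtr(-eta_old))
                np.add.at(delta, person_of_day, ll)
            acc = np.log(rng.random(n)) < delta
            u[acc] = u_prop[acc]
            accept_sum += float(acc.mean())
            mh_steps += 1
        else:
            u = u_prop

        # --- redraw probit latents given u: truncated normal around the
        # conditional mean given the daily residuals (sign-exact sampling)
        mean_all = mu_fix + u[person_of_day]
        if len(probit_idx) and len(daily_amount_idx):
            ed = W[:, daily_amount_idx] - mean_all[:, daily_amount_idx]
        for j, k in enumerate(probit_idx):
            c = consumed[parts[k][0]]
            shift = ed @ c_probit[j] if len(daily_amount_idx) else 0.0
            m_k = mean_all[:, k] + shift
            a = -m_k / s_probit[j]
            logu = np.log(rng.random(N))
            upper = -special.ndtri_exp(special.log_ndtr(-a) + logu)
            lower = special.ndtri_exp(special.log_ndtr(a) + logu)
            z = np.where(c, np.maximum(upper, a), np.minimum(lower, a))
            W[:, k] = m_k + s_probit[j] * z

        # --- fixed effects, part by part conditional on the others
        Eu = W - u[person_of_day]
        for k in range(P):
            v_k = 1.0 / lam_e[k, k]
            resk = Eu - X @ beta
            # conditional mean of part k's residual is -v_k * sum_{j!=k}
            # Lambda_kj r_j; moving it to the left gives the GLS target
            adj = resk @ lam_e[:, k] - resk[:, k] * lam_e[k, k]
            ystar = Eu[:, k] + v_k * adj
            bhat = np.linalg.lstsq(X, ystar, rcond=None)[0]
            z = rng.standard_normal(p)
            beta[:, k] = bhat + np.sqrt(v_k) * np.linalg.solve(XtX_chol.T, z)

        # --- covariances
        su = u.T @ u
        sigma_u = np.atleast_2d(
            stats.invwishart.rvs(df=nu0 + n, scale=S0_u + su, random_state=rng)
        )
        if len(probit_idx):
            # consumption-propensity random effects kept independent of the
            # rest: their covariances are not identifiable from 2-3 recalls
            # and drift to the Cauchy-Schwarz cap if left free.  Population
            # frequency-amount association still enters through each
            # person's own count and amount data.
            keep_diag = np.diag(sigma_u)[probit_idx].copy()
            sigma_u[probit_idx, :] = 0.0
            sigma_u[:, probit_idx] = 0.0
            sigma_u[probit_idx, probit_idx] = keep_diag
        R = W - X @ beta - u[person_of_day]
        RB = R[:, anchored]
        sigma_B = np.atleast_2d(
            stats.invwishart.rvs(df=nB + 2 + N, scale=S0_B + RB.T @ RB, random_state=rng)
        )
        if len(probit_idx):
            # restore unit probit variances (parameter expansion) and zero
            # the probit-probit covariances (kept out of the model so the
            # collapsed u-step stays a product of univariate probits)
            d = np.ones(P)
            d[probit_idx] = 1.0 / np.sqrt(np.diag(sigma_B)[probit_in_B])
            W *= d
            u *= d
            beta *= d
            sigma_u = sigma_u * np.outer(d, d)
            dB = d[anchored]
            sigma_B = sigma_B * np.outer(dB, dB)
            sigma_B = _project_anchored_cov(sigma_B, probit_in_B)
        for j, k in enumerate(episodic_amount_idx):
            ss = float(np.sum(R[:, k] ** 2))
            var_ep[j] = stats.invgamma.rvs(
                a0_ep + N / 2.0, scale=b0_ep + ss / 2.0, random_state=rng
            )
        sigma_e = _assemble_sigma_e()

        if it >= spec.n_burn:
            diag_u_trace[it - spec.n_burn] = np.diag(sigma_u)
            if (it - spec.n_burn) % spec.thin == 0 and keep < n_keep:
                u_draws[keep] = u
                beta_draws[keep] = beta
                sigma_e_draws[keep] = sigma_e
                sigma_u_sum += sigma_u
                sigma_e_sum += sigma_e
                keep += 1

    u_draws = u_draws[:keep]
    beta_draws = beta_draws[:keep]
    sigma_e_draws = sigma_e_draws[:keep]

    rhat = _split_rhat(diag_u_trace)
    bad = {parts[k][0] + ":" + parts[k][1]: r for k, r in rhat.items() if r > 1.2}
    if bad:
        logger.warning("possible non-convergence (split R-hat > 1.2): %s", bad)

    # per-participant design row at the typical day
    first_rows = np.unique(person_of_day, return_index=True)[1]
    X_usual = X[first_rows].copy()
    for j, name in enumerate(col_names):
        t = typical.get(name)
        if t is not None:
            X_usual[:, j] = t

    return _BlockFit(
        variables=variables,
        episodic=list(episodic),
        parts=parts,
        lambdas=lambdas,
        scale=scale,
        col_names=col_names,
        typical=typical,
        participant_ids=uniq_pid,
        X_usual=X_usual,
        u_draws=u_draws,
        beta_draws=beta_draws,
        sigma_e_draws=sigma_e_draws,
        sigma_u_mean=sigma_u_sum / max(keep, 1),
        sigma_e_mean=sigma_e_sum / max(keep, 1),
        rhat={parts[k][0] + ":" + parts[k][1]: r for k, r in rhat.items()},
        mh_accept=accept_sum / mh_steps if mh_steps else np.nan,
    )


def _project_anchored_cov(sigma, probit_in_B, eps=1e-6) -> np.ndarray:
    """Project the anchored within-day covariance onto its constraint set.

    Alternates zeroing probit-probit off-diagonals with clipping to the
    PSD cone, then rescales probit variances back to exactly 1 (the
    rescale preserves the zeros).
    """
    s = sigma.copy()
    pp = np.ix_(probit_in_B, probit_in_B)
    mask = ~np.eye(len(probit_in_B), dtype=bool)
    for _ in range(50):
        s[pp] = np.where(mask, 0.0, s[pp])
        vals = np.linalg.eigvalsh(s)
        if vals.min() > eps / 10:
            break
        ev, Q = np.linalg.eigh(s)
        s = Q @ np.diag(np.clip(ev, eps, None)) @ Q.T
    s[pp] = np.where(mask, 0.0, s[pp])
    d = np.ones(len(s))
    d[probit_in_B] = 1.0 / np.sqrt(np.diag(s)[probit_in_B])
    return s * np.outer(d, d)


def _split_rhat(trace: np.ndarray) -> dict:
    """Split-chain R-hat per column of a (n_iter, k) trace."""
    m = trace.shape[0] // 2
    if m < 2:
        return {k: np.nan for k in range(trace.shape[1])}
    halves = np.stack([trace[:m], trace[m : 2 * m]])  # (2, m, k)
    means = halves.mean(axis=1)
    vars_ = halves.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = m * means.var(axis=0, ddof=1)
    var_plus = (m - 1) / m * W + B / m
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    return {k: float(r[k]) for k in range(trace.shape[1])}


@dataclass
class FittedMEModel:
    spec: MEModelSpec
    strata: dict  # stratum label -> list of _BlockFit
    stratum_var: str | None

    @property
    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for label, blocks in self.strata.items():
            for bi, b in enumerate(blocks):
                for part, r in b.rhat.items():
                    rows.append(
                        {"stratum": label, "block": bi, "part": part, "rhat": r}
                    )
        return pd.DataFrame(rows)


def _partition_blocks(episodic, daily, spec: MEModelSpec):
    """Split food variables into blocks of at most ``max_block_foods``;
    energy and cost ride along in every block so each food keeps its
    correlation with them."""
    foods = [v for v in list(episodic) + list(daily) if v not in ("energy", "cost")]
    if len(foods) <= spec.max_block_foods:
        chunks = [foods]
    else:
        n_blocks = int(np.ceil(len(foods) / spec.max_block_foods))
        chunks = [list(c) for c in np.array_split(foods, n_blocks)]
    blocks = []
    for chunk in chunks:
        ep = [v for v in chunk if v in episodic]
        dl = [v for v in chunk if v in daily] + ["energy", "cost"]
        blocks.append((ep, dl))
    return blocks


def fit(spec: MEModelSpec, wide: pd.DataFrame, cohort: pd.DataFrame) -> FittedMEModel:
    """Fit the measurement-error model, stratified and (if needed) blocked.

    ``wide`` is the output of :func:`recalls_to_wide`: one row per
    participant-recall with food amounts, energy and cost.
    """
    for v in spec.episodic_vars + spec.daily_vars:
        if v not in wide.columns:
            raise ValueError(f"variable {v!r} not in recall table")
    reps = wide.groupby("participant_id").size()
    if not (reps >= 2).any():
        raise ValueError("measurement-error model needs replicate recalls")

    meta = cohort.set_index("participant_id")
    if spec.strata is None:
        groups = {"all": wide}
    else:
        lab = meta.loc[wide["participant_id"], spec.strata].to_numpy()
        groups = {str(s): wide[lab == s] for s in pd.unique(lab)}

    blocks_def = _partition_blocks(spec.episodic_vars, spec.daily_vars, spec)
    out = {}
    rng = np.random.default_rng(spec.seed)
    for label in sorted(groups):
        g = groups[label]
        if g["participant_id"].nunique() < spec.min_stratum:
            raise ValueError(
                f"stratum {label!r} has fewer than {spec.min_stratum} participants"
            )
        fits = []
        for ep, dl in blocks_def:
            sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            fits.append(_gibbs_block(g, cohort, ep, dl, spec, sub_rng))
        out[label] = fits
        logger.info("fitted stratum %s: %d block(s)", label, len(fits))
    return FittedMEModel(spec=spec, strata=out, stratum_var=spec.strata)


# ---------------------------------------------------------------------------
# Monte Carlo simulation of pseudo-individuals


def _usual_from_draws(block: _BlockFit, draw_idx: np.ndarray, spec: MEModelSpec) -> dict:
    """Usual values (original scale) per participant x pseudo draw.

    Returns {variable: (n, n_pseudo) array}.
    """
    n = len(block.participant_ids)
    K = block.u_draws.shape[0]
    P = len(block.parts)
    part_index = {pt: k for k, pt in enumerate(block.parts)}
    out = {}
    # linear predictor at the typical day per draw: (n_draw_used, n, P)
    usual = {v: np.zeros((n, draw_idx.shape[1])) for v in block.variables}
    for m in range(draw_idx.shape[1]):
        t = draw_idx[:, m]  # (n,) posterior-draw index per participant
        beta = block.beta_draws[t]  # (n, p, P)
        u = block.u_draws[t, np.arange(n)]  # (n, P)
        sig_e = block.sigma_e_draws[t]  # (n, P, P)
        lin = np.einsum("np,npk->nk", block.X_usual, beta) + u  # (n, P)
        for v in block.variables:
            ka = part_index[(v, "amount")]
            mu0, sd0 = block.scale[v]
            lam = block.lambdas[v]
            m_orig = mu0 + sd0 * lin[:, ka]
            var_orig = sd0**2 * sig_e[:, ka, ka]
            amt = _backtransform_mean(m_orig, var_orig, lam, spec.backtransform)
            if v in block.episodic:
                kp = part_index[(v, "prob")]
                prob = special.ndtr(lin[:, kp])
                amt = prob * amt
            usual[v][:, m] = np.maximum(amt, 0.0)
    return usual


def simulate_usual(
    fitted: FittedMEModel,
    cohort: pd.DataFrame,
    n_pseudo: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the pseudo-population of usual intake/cost vectors.

    For each participant, ``n_pseudo`` posterior draws of their random
    effects are taken (resampled from the stored MCMC draws, which are
    draws from the conditional distribution given that participant's
    recalls) and converted to usual values on the original scale.  Energy
    and cost come from the first block; foods from the block that models
    them.  Each pseudo-individual carries weight
    ``balancing_weight / n_pseudo``.
    """
    n_pseudo = n_pseudo or fitted.spec.n_pseudo
    rng = np.random.default_rng(seed)
    meta = cohort.set_index("participant_id")
    frames = []
    for label, blocks in fitted.strata.items():
        pids = blocks[0].participant_ids
        n = len(pids)
        values = {}
        for bi, block in enumerate(blocks):
            K = block.u_draws.shape[0]
            draw_idx = rng.integers(0, K, size=(n, n_pseudo))
            usual = _usual_from_draws(block, draw_idx, fitted.spec)
            for v, arr in usual.items():
                if v in ("energy", "cost") and bi > 0:
                    continue  # keep the first block's energy/cost
                values[v] = arr
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(pids, n_pseudo),
                "pseudo_index": np.tile(np.arange(n_pseudo), n),
            }
        )
        for v, arr in values.items():
            df[v] = arr.reshape(-1)
        df["weight"] = (
            meta.loc[df["participant_id"], "balancing_weight"].to_numpy() / n_pseudo
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "pseudo_index"], ignore_index=True)


def usual_summaries(
    pseudo: pd.DataFrame,
    variables: list[str] | None = None,
    percentiles: tuple = (5, 25, 50, 75, 95),
) -> pd.DataFrame:
    """Weighted mean and percentiles of each usual variable over the
    pooled pseudo-population."""
    from .regression import weighted_quantile

    if variables is None:
        variables = [
            c
            for c in pseudo.columns
            if c not in ("participant_id", "pseudo_index", "weight")
        ]
    w = pseudo["weight"].to_numpy(dtype=float)
    rows = []
    for v in variables:
        x = pseudo[v].to_numpy(dtype=float)
        row = {"variable": v, "mean": float(np.sum(w * x) / np.sum(w))}
        for p in percentiles:
            row[f"p{p}"] = float(weighted_quantile(x, p, w))
        rows.append(row)
    return pd.DataFrame(rows)
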