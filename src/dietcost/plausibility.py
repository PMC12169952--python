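"""Plausibility screening of self-reported energy intake.

Mean reported energy intake (EI) over the completed 24-h recalls is
compared with the predicted energy requirement (pEER) from the
Institute of Medicine adult equations, assuming a lightly active
physical activity level.  Following the Huang et al. approach, a
participant is flagged as an under- (over-) reporter when the ratio
100*EI/pEER falls more than one standard deviation below (above) 100,
where the SD aggregates three sources of disagreement expected even
under truthful reporting::

    sd% = sqrt(CV_wEI^2 / n_recalls + CV_pEER^2 + CV_TEE^2)

with CV_wEI the within-person day-to-day coefficient of variation of
reported energy, CV_pEER the error of the requirement equations and
CV_TEE the biological variability of total energy expenditure (the
Black & Cole value, 8.2 %, by default).

The classification is diagnostic only: flagged participants are
reported, not excluded from downstream analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "predicted_eer",
    "plausibility_cutoff",
    "estimate_within_cv_energy",
    "classify",
]

# IOM (2002/2005) adult EER physical-activity coefficients
_PA = {
    "M": {"sedentary": 1.00, "low_active": 1.11, "active": 1.25, "very_active": 1.48},
    "F": {"sedentary": 1.00, "low_active": 1.12, "active": 1.27, "very_active": 1.45},
}

CV_TEE_DEFAULT = 8.2  # % biological variability of total energy expenditure
CV_PEER_DEFAULT = 8.2  # % error of the predictive equations


def predicted_eer(sex, age, weight_kg, height_m, pal: str = "low_active"):
    """IOM adult estimated energy requirement, kcal/d.

    men:   EER = 662 - 9.53*age + PA*(15.91*weight + 539.6*height)
    women: EER = 354 - 6.91*age + PA*(9.36*weight + 726*height)

    ``sex`` is "M"/"F" (arrays allowed); weight in kg, height in metres.
    """
    sex = np.atleast_1d(np.asarray(sex, dtype=object))
    age = np.broadcast_to(np.asarray(age, dtype=float), sex.shape)
    wt = np.broadcast_to(np.asarray(weight_kg, dtype=float), sex.shape)
    ht = np.broadcast_to(np.asarray(height_m, dtype=float), sex.shape)
    out = np.empty(sex.shape)
    for s in ("M", "F"):
        mask = sex == s
        if not mask.any():
            continue
        pa = _PA[s][pal]
        if s == "M":
            out[mask] = 662.0 - 9.53 * age[mask] + pa * (
                15.91 * wt[mask] + 539.6 * ht[mask]
            )
        else:
            out[mask] = 354.0 - 6.91 * age[mask] + pa * (
                9.36 * wt[mask] + 726.0 * ht[mask]
            )
    unknown = ~np.isin(sex, ("M", "F"))
    if unknown.any():
        raise ValueError(f"sex must be 'M' or 'F', got {set(sex[unknown])}")
    return out if out.size > 1 else float(out[0])


def plausibility_cutoff(
    cv_within_ei_pct: float,
    n_recalls: int,
    cv_peer_pct: float = CV_PEER_DEFAULT,
    cv_tee_pct: float = CV_TEE_DEFAULT,
) -> float:
    """One-SD half-width (percent) of the EI/pEER agreement band."""
    if n_recalls < 1:
        raise ValueError("n_recalls must be >= 1")
    return float(
        np.sqrt(
            cv_within_ei_pct**2 / n_recalls + cv_peer_pct**2 + cv_tee_pct**2
        )
    )


def estimate_within_cv_energy(daily_energy: pd.DataFrame) -> float:
    """Within-person CV (%) of daily energy from replicate recalls.

    One-way random-effects decomposition on the log scale: the pooled
    within-person variance of log energy, s2w, gives CV = sqrt(exp(s2w)-1).
    An approximation to the reference univariate approach, adequate for
    setting the plausibility band.
    """
    g = daily_energy.groupby("participant_id")["energy_kcal"]
    counts = g.count()
    if (counts < 2).all():
        raise ValueError("need at least one participant with >= 2 recalls")
    logs = np.log(daily_energy["energy_kcal"].astype(float))
    resid = logs - daily_energy["participant_id"].map(g.apply(lambda x: np.log(x).mean()))
    dof = int((counts - 1).sum())
    s2w = float(np.sum(resid**2) / dof)
    return float(np.sqrt(np.exp(s2w) - 1.0) * 100.0)


def classify(
    cohort: pd.DataFrame,
    daily_energy: pd.DataFrame,
    pal: str = "low_active",
    cv_within_ei_pct: float | None = None,
    cv_peer_pct: float = CV_PEER_DEFAULT,
    cv_tee_pct: float = CV_TEE_DEFAULT,
    k: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Classify each participant's reported energy as under/plausible/over.

    Parameters
    ----------
    cohort
        Needs participant_id, sex, age, weight_kg, height_m and
        balancing_weight columns.
    daily_energy
        Per participant-day energy (participant_id, energy_kcal), one row
        per completed recall.
    cv_within_ei_pct
        Within-person CV of energy; estimated from ``daily_energy`` via
        :func:`estimate_within_cv_energy` when omitted.
    k
        Number of SDs delimiting the plausible band (1 by default).

    Returns
    -------
    (per-person results frame, summary dict with weighted fractions).
    """
    if daily_energy.empty:
        raise ValueError("no recall energy data to classify")
    g = daily_energy.groupby("participant_id")["energy_kcal"]
    mean_ei = g.mean()
    n_recalls = g.count()
    if cv_within_ei_pct is None:
        cv_within_ei_pct = estimate_within_cv_energy(daily_energy)

    coh = cohort.set_index("participant_id").loc[mean_ei.index]
    peer = predicted_eer(
        coh["sex"].to_numpy(),
        coh["age"].to_numpy(),
        coh["weight_kg"].to_numpy(),
        coh["height_m"].to_numpy(),
        pal=pal,
    )
    peer = np.atleast_1d(peer)
    ratio = 100.0 * mean_ei.to_numpy() / peer
    sd_pct = np.array(
        [
            plausibility_cutoff(cv_within_ei_pct, int(n), cv_peer_pct, cv_tee_pct)
            for n in n_recalls.to_numpy()
        ]
    )
    cls = np.where(
        ratio < 100.0 - k * sd_pct,
        "under",
        np.where(ratio > 100.0 + k * sd_pct, "over", "plausible"),
    )
    res = pd.DataFrame(
        {
            "participant_id": mean_ei.index,
            "mean_reported_EI": mean_ei.to_numpy(),
            "predicted_EER": peer,
            "ratio_pct": ratio,
            "cutoff_sd_pct": sd_pct,
            "class": cls,
        }
    )
    w = coh["balancing_weight"].to_numpy(dtype=float)
    summary = {
        "cv_within_ei_pct": float(cv_within_ei_pct),
        "n": int(len(res)),
        "frac_under": float(w[cls == "under"].sum() / w.sum()),
        "frac_plausible": float(w[cls == "plausible"].sum() / w.sum()),
        "frac_over": float(w[cls == "over"].sum() / w.sum()),
    }
    return res, summary
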