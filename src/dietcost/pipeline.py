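"""End-to-end orchestration of the diet-cost study.

One call (or one CLI invocation) runs the full chain on synthetic or
user-supplied data: covariate imputation, balancing weights, food-group
pricing, daily diet costs, energy-reporting plausibility, the
measurement-error model and pseudo-population, dietary-index scoring,
and the spline regressions with bootstrap confidence intervals --
overall, with and without energy adjustment, per component, and by
sociodemographic subgroup.  All randomness flows from the seeds in the
configuration; re-running with the same configuration reproduces every
number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    eat_index,
    measurement_error as me,
    plausibility,
    price_engine,
    regression,
    synthetic_data as synth,
)

__all__ = ["StudyConfig", "impute_fcs", "run_study", "score_pseudo_population", "oracle_contrast"]

logger = logging.getLogger(__name__)

#: knot percentiles for right-skewed component score distributions
SKEWED_KNOTS = (10, 50, 90)
SKEWED_COMPONENTS = ("tubers_starchy_vegetables", "vegetables", "fruits")
LINEAR_COMPONENTS = ("dairy",)


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    n_participants: int = 1147
    seed: int = 20150801
    n_recalls: int = 3
    # measurement-error model
    n_pseudo: int = 500
    n_iter: int = 4000
    n_burn: int = 2000
    thin: int = 4
    # regression
    n_boot: int = 200
    knot_percentiles: tuple = (5, 35, 65, 95)
    p_hi: float = 75.0
    p_lo: float = 25.0
    # pricing
    n_stores: int = 6
    price_dispersion: float = 0.05
    missing_price_groups: tuple = ("legumes_nuts", "added_fats_unsat")
    output_dir: str | None = None
    eat_spec_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for k in ("knot_percentiles", "missing_price_groups"):
            if k in known and known[k] is not None:
                known[k] = tuple(known[k])
        return cls(**known)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def impute_fcs(
    cohort: pd.DataFrame,
    variables: tuple = ("income", "education"),
    predictors: tuple = ("sex", "age_group", "region", "smoking"),
    n_cycles: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Single imputation of categorical covariates by chained equations.

    Each incomplete variable is imputed from a multinomial logistic model
    on the predictors plus the other (currently filled) imputed
    variables, drawing categories from the predicted probabilities, and
    the cycle is repeated ``n_cycles`` times.  Missingness flags are
    retained in ``<var>_missing`` columns.
    """
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(seed)
    out = cohort.copy()
    missing = {v: out[v].isna().to_numpy() for v in variables}
    if not any(m.any() for m in missing.values()):
        for v in variables:
            out[f"{v}_missing"] = False
        return out

    # initial fill: draw from the observed marginal
    for v in variables:
        out[f"{v}_missing"] = missing[v]
        if missing[v].any():
            obs = out.loc[~missing[v], v]
            out.loc[missing[v], v] = rng.choice(
                obs.unique(), size=missing[v].sum(), p=obs.value_counts(normalize=True)[obs.unique()].to_numpy()
            )

    for _ in range(n_cycles):
        for v in variables:
            if not missing[v].any():
                continue
            others = [o for o in variables if o != v]
            Xdf = pd.get_dummies(out[list(predictors) + others], drop_first=True)
            X = Xdf.to_numpy(dtype=float)
            y = out[v].to_numpy()
            model = LogisticRegression(max_iter=500)
            model.fit(X[~missing[v]], y[~missing[v]])
            proba = model.predict_proba(X[missing[v]])
            cum = np.cumsum(proba, axis=1)
            draws = (rng.random((missing[v].sum(), 1)) < cum).argmax(axis=1)
            out.loc[missing[v], v] = model.classes_[draws]
    return out


def score_pseudo_population(
    pseudo: pd.DataFrame, spec: eat_index.EatISpec | None = None
) -> pd.DataFrame:
    """Attach dietary-index scores to the pseudo-population.

    Returns a frame with participant_id, pseudo-index, weight, usual cost
    and energy, the total score and one column per main component score.
    """
    food_cols = [
        c
        for c in pseudo.columns
        if c not in ("participant_id", "pseudo_index", "weight", "energy", "cost")
    ]
    scores = eat_index.score_total(pseudo[food_cols], pseudo["energy"].to_numpy(), spec)
    out = pseudo[["participant_id", "pseudo_index", "weight", "cost", "energy"]].copy()
    out["score_total"] = scores["total"].to_numpy()
    for c in scores.columns:
        if c != "total":
            out[f"score_{c}"] = scores[c].to_numpy()
    return out


def oracle_contrast(
    truth_table: pd.DataFrame,
    config: StudyConfig | None = None,
    energy_adjust: bool = True,
) -> regression.SplineContrast:
    """The true score-cost contrast, fitted on true usual intakes.

    Applies the same spline machinery directly to the truth table from
    the synthetic generator; the resulting P75-P25 cost difference is the
    oracle for end-to-end pipeline recovery.
    """
    config = config or StudyConfig()
    data = pd.DataFrame(
        {
            "participant_id": truth_table["participant_id"],
            "cost": truth_table["true_cost"],
            "energy": truth_table["true_energy"],
            "weight": truth_table["balancing_weight"],
            "score_total": truth_table["true_score"],
        }
    )
    cfg = regression.SplineConfig(
        knot_percentiles=config.knot_percentiles,
        energy_adjust=energy_adjust,
        p_hi=config.p_hi,
        p_lo=config.p_lo,
        n_boot=config.n_boot,
        seed=config.seed + 77,
    )
    return regression.bootstrap_contrast(data, "score_total", cfg)


def _component_spline_config(component: str, config: StudyConfig, seed: int) -> regression.SplineConfig:
    return regression.SplineConfig(
        knot_percentiles=SKEWED_KNOTS
        if component in SKEWED_COMPONENTS
        else config.knot_percentiles,
        linear_only=component in LINEAR_COMPONENTS,
        energy_adjust=True,
        p_hi=config.p_hi,
        p_lo=config.p_lo,
        n_boot=config.n_boot,
        seed=seed,
    )


def run_study(config: StudyConfig | None = None) -> dict:
    """Run the whole analysis chain on a synthetic cohort.

    Returns a dict of result tables; when ``config.output_dir`` is set
    they are also written as CSV/JSON with run metadata (config hash and
    seeds).
    """
    config = config or StudyConfig()
    seed = config.seed
    logger.info("study run, config hash %s", config.config_hash())

    # --- synthetic study data with known truth
    cc = synth.CohortConfig(
        n_participants=config.n_participants, n_recalls=config.n_recalls, seed=seed
    )
    cohort, truth = synth.generate_cohort(cc)
    recalls = synth.generate_recalls(cohort, truth, cc)
    sales = synth.generate_sales_db(
        cc.food_specs,
        n_stores=config.n_stores,
        dispersion=config.price_dispersion,
        seed=seed + 2,
        missing_groups=config.missing_price_groups,
    )
    eat_spec = (
        eat_index.load_spec(config.eat_spec_path)
        if config.eat_spec_path
        else eat_index.default_eat_i_spec()
    )

    # --- imputation of missing sociodemographics
    cohort_imp = impute_fcs(cohort, seed=seed + 3)

    # --- prices and daily costs
    price_table = price_engine.build_price_table(sales)
    price_table = price_engine.fill_missing_prices(
        price_table,
        all_groups=[s.name for s in cc.food_specs],
        categories={s.name: s.category for s in cc.food_specs},
        referenced_groups=recalls["food_group"].unique(),
    )
    daily_costs = price_engine.cost_recalls(recalls, price_table)
    weights = cohort.set_index("participant_id")["balancing_weight"]
    cost2500 = price_engine.energy_adjusted_cost(daily_costs, weights)

    # --- plausibility of reported energy (diagnostic only)
    plaus, plaus_summary = plausibility.classify(
        cohort, daily_costs.rename(columns={"energy_kcal": "energy_kcal"})[
            ["participant_id", "energy_kcal"]
        ],
    )

    # --- measurement-error model and pseudo-population
    episodic, daily = me.classify_episodic(recalls, weights)
    wide = me.recalls_to_wide(recalls, daily_costs)
    me_spec = me.MEModelSpec(
        episodic_vars=episodic,
        daily_vars=daily + ["energy", "cost"],
        n_pseudo=config.n_pseudo,
        n_iter=config.n_iter,
        n_burn=config.n_burn,
        thin=config.thin,
        seed=seed + 4,
    )
    fitted = me.fit(me_spec, wide, cohort_imp)
    pseudo = me.simulate_usual(fitted, cohort_imp, seed=seed + 5)
    scored = score_pseudo_population(pseudo, eat_spec)

    # --- population mean score (ratio method) and usual summaries
    food_cols = [
        c
        for c in pseudo.columns
        if c not in ("participant_id", "pseudo_index", "weight", "energy", "cost")
    ]
    mean_score = eat_index.population_ratio_mean(
        pseudo[food_cols],
        pseudo["energy"].to_numpy(),
        pseudo["weight"].to_numpy(),
        eat_spec,
        participant_ids=pseudo["participant_id"].to_numpy(),
        n_boot=config.n_boot,
        seed=seed + 6,
    )
    summaries = me.usual_summaries(pseudo)

    # --- overall contrasts, with and without energy adjustment
    contrasts = []
    for adjust in (False, True):
        cfg = regression.SplineConfig(
            knot_percentiles=config.knot_percentiles,
            energy_adjust=adjust,
            p_hi=config.p_hi,
            p_lo=config.p_lo,
            n_boot=config.n_boot,
            seed=seed + 7,
        )
        contrasts.append(regression.bootstrap_contrast(scored, "score_total", cfg))

    # --- per-component contrasts (energy-adjusted)
    component_rows = []
    for comp in [c.name for c in eat_spec.components]:
        col = f"score_{comp}"
        cfg = _component_spline_config(comp, config, seed + 8)
        res = regression.bootstrap_contrast(scored, col, cfg)
        component_rows.append(res)

    # --- subgroup analyses on the total score, energy-adjusted
    sub_cfg = regression.SplineConfig(
        knot_percentiles=config.knot_percentiles,
        energy_adjust=True,
        p_hi=config.p_hi,
        p_lo=config.p_lo,
        n_boot=config.n_boot,
        seed=seed + 9,
    )
    subgroups = regression.subgroup_contrasts(scored, "score_total", sub_cfg, cohort_imp)

    # --- oracle from the generator's truth
    truth_table = synth.oracle_truth(cohort, truth, cc.food_specs, eat_spec)
    oracle = oracle_contrast(truth_table, config)

    def _contrast_frame(items):
        return pd.DataFrame(
            [
                {
                    "score_variable": r.score_variable,
                    "energy_adjusted": r.energy_adjusted,
                    "delta_cost": r.delta_cost,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "se": r.se,
                    "n_boot": r.n_boot,
                    "x_lo": r.x_lo,
                    "x_hi": r.x_hi,
                    "n": r.n,
                    "skipped": r.skipped,
                }
                for r in items
            ]
        )

    results = {
        "cohort": cohort_imp,
        "price_table": price_table,
        "daily_costs": daily_costs,
        "cost_per_2500kcal": cost2500,
        "plausibility": plaus,
        "plausibility_summary": plaus_summary,
        "pseudo_population": pseudo,
        "scored_pseudo": scored,
        "mean_eat_i": mean_score,
        "usual_summaries": summaries,
        "overall_contrasts": _contrast_frame(contrasts),
        "component_contrasts": _contrast_frame(component_rows),
        "subgroup_contrasts": subgroups,
        "truth_table": truth_table,
        "oracle_contrast": oracle,
        "me_diagnostics": fitted.diagnostics,
        "meta": {
            "config_hash": config.config_hash(),
            "seed": seed,
            "episodic_vars": episodic,
            "daily_vars": daily,
            "weighted_mean_cost_per_2500kcal": cost2500.attrs.get("weighted_mean"),
        },
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        meta = dict(results["meta"])
        meta["mean_eat_i"] = results["mean_eat_i"]
        meta["plausibility_summary"] = results["plausibility_summary"]
        with open(outdir / "run_meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, default=str)
        logger.info("results written to %s", outdir)
    return results
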