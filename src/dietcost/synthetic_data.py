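"""Synthetic cohort, recall and price data with known ground truth.

Emulates the structure of a web-based 24-h recall study of French-speaking
adults with stratified sampling (region x sex x age group), three recalls
per person over three weeks, and a grocery-chain sales database used to
price food groups:

* person-level *usual* (long-run average) intakes per food group, drawn
  log-normally with a controllable between-person correlation structure --
  a single "diet quality" factor by default, so that people who eat more
  vegetables, fruits and fish also drink fewer sugary drinks; this is the
  lever that creates a known score-cost relationship;
* episodic food groups with never-consumers and day-to-day consumption
  probabilities, producing realistic zero inflation in single-day recalls;
* within-person day-to-day log-normal noise, a first-recall sequence
  effect and a weekend effect (Friday counts as a weekend day);
* person-level under/over-reporting as a multiplicative factor on all
  reported amounts (20 % of people at x0.75 and 15 % at x1.25 by default);
* usual energy scaled to each person's predicted energy requirement, so
  reported energy is interpretable against requirement-based plausibility
  cut-offs;
* an annual sales table (dollars, kg) per food group and store whose
  pooled ratio recovers the true consumer price, with a configurable set
  of groups missing from the sales data.

Every stage is seeded and deterministic, and the truth table (true usual
intakes, energy, cost and true dietary-index score per participant) makes
the full pipeline testable against a known answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import plausibility

__all__ = [
    "FoodGroupSpec",
    "CohortConfig",
    "default_food_specs",
    "default_strata",
    "generate_cohort",
    "generate_recalls",
    "generate_sales_db",
    "oracle_truth",
    "nearest_correlation",
]

WEEKEND_DAYS_PER_WEEK = 3.0 / 7.0  # Friday, Saturday, Sunday


@dataclass(frozen=True)
class FoodGroupSpec:
    """Generative parameters for one food group.

    ``mean_usual`` is the typical usual intake (kg/d, long-run mean
    including non-consumption days) among consumers of the group;
    between-person variation is log-normal with ``sd_log_usual_between``;
    recalls add log-normal day-to-day noise with ``sd_log_within``.  A
    fraction ``1 - p_consumer`` of people never consume an episodic group,
    and consumers consume it on a given day with ``p_day_given_consumer``.
    """

    name: str
    episodic: bool
    mean_usual: float  # kg/d among consumers
    sd_log_usual_between: float
    sd_log_within: float
    energy_density: float  # kcal/kg
    true_price: float  # $CAD/kg
    p_consumer: float = 1.0
    p_day_given_consumer: float = 1.0
    category: str = "other"
    factor_loading: float = 0.0  # loading on the diet-quality factor

    def __post_init__(self) -> None:
        for p in (self.p_consumer, self.p_day_given_consumer):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probabilities must be in [0,1]")
        if min(self.sd_log_usual_between, self.sd_log_within) < 0:
            raise ValueError(f"{self.name}: sds must be >= 0")
        if self.energy_density < 0 or self.true_price < 0:
            raise ValueError(f"{self.name}: energy density and price must be >= 0")
        if not self.episodic and self.p_day_given_consumer < 1.0:
            raise ValueError(f"{self.name}: daily groups need p_day_given_consumer=1")


def default_food_specs() -> list[FoodGroupSpec]:
    """Thirteen synthetic food groups mapped onto the dietary-index components.

    Prices and energy densities are round, plausible Canadian grocery
    figures chosen so that nutrient-dense foods (vegetables, fruits, fish,
    nuts) are expensive per calorie and refined grains / sugary products
    are cheap per calorie.  Factor loadings put vegetables, fruits, fish
    and whole grains on the "healthy" pole and sugary drinks and refined
    grains on the other, with poultry & eggs loading with the expensive
    pole (so greater adherence to that in-range component tracks cheaper
    diets), echoing the qualitative pattern seen in consumer data.
    """
    rows = [
        # name, episodic, p_cons, p_day, usual, sd_b, sd_w, kcal/kg, $/kg, category, loading
        ("whole_grains", True, 0.95, 0.70, 0.060, 0.45, 0.55, 2500, 4.0, "grains", 0.40),
        ("refined_grains", False, 1.0, 1.0, 0.150, 0.35, 0.45, 2800, 3.0, "grains", -0.45),
        ("tubers", True, 0.95, 0.55, 0.080, 0.45, 0.60, 800, 2.0, "vegetables", -0.10),
        ("vegetables", True, 1.0, 0.85, 0.200, 0.40, 0.45, 350, 7.0, "vegetables", 0.60),
        ("fruits", True, 0.98, 0.75, 0.150, 0.45, 0.55, 550, 6.0, "fruits", 0.55),
        ("dairy", False, 1.0, 1.0, 0.250, 0.40, 0.45, 650, 4.0, "dairy", 0.05),
        ("red_processed_meat", True, 0.97, 0.55, 0.080, 0.40, 0.60, 2200, 14.0, "meats", -0.30),
        ("poultry_eggs", True, 0.98, 0.60, 0.090, 0.40, 0.60, 1800, 7.0, "meats", 0.35),
        ("fish_seafood", True, 0.90, 0.30, 0.030, 0.50, 0.70, 1500, 18.0, "meats", 0.50),
        ("legumes_nuts", True, 0.92, 0.50, 0.035, 0.50, 0.65, 3500, 9.0, "plant_proteins", 0.45),
        ("added_fats_sat", True, 0.95, 0.65, 0.020, 0.40, 0.55, 7400, 6.0, "fats", -0.25),
        ("added_fats_unsat", True, 0.95, 0.70, 0.025, 0.40, 0.55, 8800, 8.0, "fats", 0.30),
        ("sweets_sugary_drinks", False, 1.0, 1.0, 0.300, 0.50, 0.50, 2000, 2.5, "sweets", -0.60),
    ]
    return [
        FoodGroupSpec(
            name=n,
            episodic=e,
            p_consumer=pc,
            p_day_given_consumer=pd_,
            mean_usual=mu,
            sd_log_usual_between=sb,
            sd_log_within=sw,
            energy_density=ed,
            true_price=pr,
            category=cat,
            factor_loading=fl,
        )
        for n, e, pc, pd_, mu, sb, sw, ed, pr, cat, fl in rows
    ]


def default_strata() -> pd.DataFrame:
    """Region x sex x age-group sampling cells with target proportions.

    Five administrative regions with population-like shares, equal sexes
    and three adult age bands.
    """
    regions = {
        "capitale_chaudiere": 0.35,
        "estrie": 0.10,
        "mauricie": 0.08,
        "montreal": 0.37,
        "saguenay": 0.10,
    }
    ages = {"18-34": 0.35, "35-49": 0.32, "50-65": 0.33}
    rows = []
    for r, pr in regions.items():
        for s in ("M", "F"):
            for a, pa in ages.items():
                rows.append({"region": r, "sex": s, "age_group": a, "proportion": pr * 0.5 * pa})
    return pd.DataFrame(rows)


@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic cohort."""

    n_participants: int = 1147
    strata: pd.DataFrame = field(default_factory=default_strata)
    n_recalls: int = 3
    seed: int = 20150801
    food_specs: list[FoodGroupSpec] = field(default_factory=default_food_specs)
    # person-level reporting bias: fractions and multiplicative factors
    under_reporter_frac: float = 0.20
    under_reporter_factor: float = 0.75
    over_reporter_frac: float = 0.15
    over_reporter_factor: float = 1.25
    # covariate missingness (set missing at random)
    missing_income_frac: float = 0.14
    missing_education_frac: float = 0.05
    mar_on_age: bool = False  # if True, missingness odds double in 18-34
    # recall effects
    sequence_effect_recall1: float = 1.05
    weekend_effect: float = 1.10
    # usual energy is scaled to predicted requirement x lognormal(0, this sd)
    energy_requirement_sd: float = 0.07
    correlation: np.ndarray | None = None  # overrides factor-loading structure

    def __post_init__(self) -> None:
        tot = float(self.strata["proportion"].sum())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"stratum proportions sum to {tot}, expected 1")
        if self.n_recalls < 2:
            raise ValueError("need n_recalls >= 2 for measurement-error modelling")
        if self.under_reporter_frac + self.over_reporter_frac > 1.0:
            raise ValueError("reporting-bias fractions exceed 1")


def nearest_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalue clipping followed by diagonal renormalization; warns when a
    repair was actually needed.
    """
    m = np.asarray(mat, dtype=float)
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    if vals.min() < eps:
        warnings.warn("correlation matrix not positive definite; applying nearest-PD repair")
        vals = np.clip(vals, eps, None)
        m = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


def _correlation_matrix(config: CohortConfig) -> np.ndarray:
    if config.correlation is not None:
        r = np.asarray(config.correlation, dtype=float)
        k = len(config.food_specs)
        if r.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        return nearest_correlation(r)
    load = np.array([s.factor_loading for s in config.food_specs])
    r = np.outer(load, load)
    np.fill_diagonal(r, 1.0)
    return nearest_correlation(r)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a stratified cohort with balancing weights and true usual intakes.

    Returns
    -------
    (cohort, truth) where ``cohort`` has one row per participant
    (sociodemographics, anthropometry, stratum, balancing weight,
    reporting-bias factor) and ``truth`` holds the true usual intake per
    food group (kg/d) plus true usual energy (kcal/d).
    """
    rng = np.random.default_rng(config.seed)
    strata = config.strata.reset_index(drop=True)
    n = config.n_participants
    counts = rng.multinomial(n, strata["proportion"].to_numpy())
    if (counts[strata["proportion"].to_numpy() <= 0] > 0).any():
        raise ValueError("participants drawn into a zero-target stratum")

    rows = []
    pid = 0
    for (idx, cell), c in zip(strata.iterrows(), counts):
        for _ in range(c):
            rows.append(
                {
                    "participant_id": pid,
                    "stratum_id": idx,
                    "region": cell["region"],
                    "sex": cell["sex"],
                    "age_group": cell["age_group"],
                }
            )
            pid += 1
    cohort = pd.DataFrame(rows)

    # post-stratification: weighted stratum shares reproduce the targets
    realized = cohort["stratum_id"].value_counts() / n
    target = strata["proportion"]
    weight_by_stratum = {
        s: float(target[s] / realized[s]) for s in realized.index
    }
    cohort["balancing_weight"] = cohort["stratum_id"].map(weight_by_stratum)

    # ages within band, anthropometry by sex
    lo = cohort["age_group"].map({"18-34": 18, "35-49": 35, "50-65": 50}).to_numpy()
    hi = cohort["age_group"].map({"18-34": 35, "35-49": 50, "50-65": 66}).to_numpy()
    cohort["age"] = np.floor(rng.uniform(lo, hi)).astype(int)
    is_m = (cohort["sex"] == "M").to_numpy()
    height = np.where(
        is_m, rng.normal(1.77, 0.07, n), rng.normal(1.635, 0.065, n)
    ).clip(1.40, 2.10)
    bmi = np.where(is_m, rng.normal(27.0, 4.5, n), rng.normal(26.5, 5.5, n)).clip(16, 55)
    cohort["height_m"] = np.round(height, 3)
    cohort["weight_kg"] = np.round(bmi * height**2, 1)

    cohort["education"] = rng.choice(
        ["none_highschool", "trade_cegep", "university"], size=n, p=[0.15, 0.40, 0.45]
    )
    cohort["income"] = rng.choice(
        ["lt30k", "30to60k", "60to90k", "ge90k"], size=n, p=[0.16, 0.25, 0.25, 0.34]
    )
    cohort["smoking"] = rng.choice(["smoker", "non_smoker"], size=n, p=[0.18, 0.82])

    for col, frac in (
        ("income", config.missing_income_frac),
        ("education", config.missing_education_frac),
    ):
        if frac > 0:
            p = np.full(n, frac)
            if config.mar_on_age:
                p = np.where(cohort["age_group"] == "18-34", np.minimum(2 * frac, 1.0), frac)
            cohort.loc[rng.random(n) < p, col] = np.nan

    # person-level reporting bias, exact counts for the two tails
    n_under = int(round(n * config.under_reporter_frac))
    n_over = int(round(n * config.over_reporter_frac))
    factors = np.ones(n)
    order = rng.permutation(n)
    factors[order[:n_under]] = config.under_reporter_factor
    factors[order[n_under : n_under + n_over]] = config.over_reporter_factor
    cohort["reporting_factor"] = factors

    # true usual intakes: correlated log-normal, with never-consumers
    specs = config.food_specs
    k = len(specs)
    corr = _correlation_matrix(config)
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    intakes = np.empty((n, k))
    for j, s in enumerate(specs):
        sd = s.sd_log_usual_between
        # median-preserving log-normal around the typical consumer intake
        intakes[:, j] = s.mean_usual * np.exp(sd * z[:, j] - sd**2 / 2.0)
        if s.episodic and s.p_consumer < 1.0:
            never = rng.random(n) >= s.p_consumer
            intakes[never, j] = 0.0

    # scale each person's diet so usual energy tracks predicted requirement
    densities = np.array([s.energy_density for s in specs])
    raw_energy = intakes @ densities
    peer = plausibility.predicted_eer(
        cohort["sex"].to_numpy(),
        cohort["age"].to_numpy(),
        cohort["weight_kg"].to_numpy(),
        cohort["height_m"].to_numpy(),
    )
    scale = np.divide(
        np.atleast_1d(peer) * np.exp(rng.normal(0.0, config.energy_requirement_sd, n)),
        raw_energy,
        out=np.ones(n),
        where=raw_energy > 0,
    )
    intakes *= scale[:, None]

    truth = pd.DataFrame(intakes, columns=[s.name for s in specs])
    truth.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    truth["true_usual_energy"] = intakes @ densities
    return cohort, truth


def generate_recalls(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate 24-h recall records for every participant.

    One row per (participant, recall, food group), zero amounts included
    (they carry the episodic signal).  Reported amounts are the person's
    true usual amount perturbed by day-to-day log-normal noise, a
    first-recall sequence effect, a weekend effect, and the person's
    reporting-bias factor; per-record energy is amount x energy density.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    specs = config.food_specs
    n = len(cohort)
    r = config.n_recalls
    pids = cohort["participant_id"].to_numpy()
    bias = cohort["reporting_factor"].to_numpy()

    weekend = rng.random((n, r)) < WEEKEND_DAYS_PER_WEEK
    frames = []
    for j, s in enumerate(specs):
        usual = truth[s.name].to_numpy()  # (n,)
        amount = np.zeros((n, r))
        consumers = usual > 0
        if s.episodic:
            eats_today = rng.random((n, r)) < s.p_day_given_consumer
            mean_when_eaten = np.divide(
                usual,
                s.p_day_given_consumer if s.p_day_given_consumer > 0 else 1.0,
                out=np.zeros_like(usual),
                where=consumers,
            )
        else:
            eats_today = np.ones((n, r), dtype=bool)
            mean_when_eaten = usual
        noise = np.exp(
            s.sd_log_within * rng.standard_normal((n, r)) - s.sd_log_within**2 / 2.0
        )
        amount = mean_when_eaten[:, None] * noise * eats_today * consumers[:, None]
        amount[:, 0] *= config.sequence_effect_recall1
        amount *= np.where(weekend, config.weekend_effect, 1.0)
        amount *= bias[:, None]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, r),
                    "recall_index": np.tile(np.arange(1, r + 1), n),
                    "weekend": weekend.ravel(),
                    "food_group": s.name,
                    "amount_kg": amount.ravel(),
                    "energy_kcal": amount.ravel() * s.energy_density,
                }
            )
        )
    recalls = pd.concat(frames, ignore_index=True)
    return recalls.sort_values(
        ["participant_id", "recall_index", "food_group"], ignore_index=True
    )


def generate_sales_db(
    food_specs: list[FoodGroupSpec],
    n_stores: int = 6,
    dispersion: float = 0.05,
    seed: int = 0,
    missing_groups: tuple[str, ...] = (),
    mean_kg_sold: float = 1e6,
) -> pd.DataFrame:
    """Simulate an annual grocery sales table (dollars and kg per store).

    Per (group, store): kilograms sold are log-normal around
    ``mean_kg_sold``; the store's unit price is the group's true price
    jittered log-normally by ``dispersion``; dollars = kg x price.  Groups
    listed in ``missing_groups`` are emitted with no rows at all, emulating
    gaps in commercial sales data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in food_specs:
        if s.name in missing_groups:
            continue
        for store in range(n_stores):
            kg = mean_kg_sold * np.exp(rng.normal(0.0, 0.5)) if dispersion > 0 else mean_kg_sold
            price = s.true_price * np.exp(rng.normal(0.0, dispersion) - dispersion**2 / 2)
            rows.append(
                {
                    "food_group": s.name,
                    "store": f"store_{store}",
                    "dollars": kg * price,
                    "kg": kg,
                }
            )
    return pd.DataFrame(rows)


def oracle_truth(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    food_specs: list[FoodGroupSpec],
    eat_spec=None,
) -> pd.DataFrame:
    """Ground-truth table: true usual cost, energy and dietary-index score.

    True usual daily cost is the inner product of true usual intakes with
    true prices; the true score applies the index to the true usual intake
    vector.  This is the oracle every downstream estimate is judged
    against.
    """
    from . import eat_index

    names = [s.name for s in food_specs]
    prices = np.array([s.true_price for s in food_specs])
    intakes = truth[names]
    out = pd.DataFrame({"participant_id": truth["participant_id"]})
    out["true_cost"] = intakes.to_numpy() @ prices
    out["true_energy"] = truth["true_usual_energy"].to_numpy()
    scores = eat_index.score_total(intakes, out["true_energy"].to_numpy(), eat_spec)
    out["true_score"] = scores["total"].to_numpy()
    for c in scores.columns:
        if c != "total":
            out[f"score_{c}"] = scores[c].to_numpy()
    out["balancing_weight"] = cohort.set_index("participant_id").loc[
        out["participant_id"], "balancing_weight"
    ].to_numpy()
    return out
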