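"""Sales-weighted food-group pricing and recall-to-cost linkage.

Consumer prices are estimated from an annual sales table (dollars and
kilograms sold per food group and store): the price of a food group is
total dollars divided by total kilograms pooled over foods and stores,
which weights each food's price by its sales volume.  Purchased prices
are converted to edible prices with yield factors (moisture and fat loss,
cooking gains), groups missing from the sales data are filled through an
ordered fallback hierarchy, and each 24-h recall day is converted to a
daily diet cost by multiplying reported amounts (kg) by group prices
($/kg) and summing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "build_price_table",
    "apply_yield",
    "fill_missing_prices",
    "cost_recalls",
    "energy_adjusted_cost",
]

logger = logging.getLogger(__name__)

#: columns of a price table
PRICE_COLUMNS = ["food_group", "price_per_kg", "provenance", "yield_factor", "total_kg"]


def build_price_table(sales: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Estimate one consumer price per food group from an annual sales table.

    Parameters
    ----------
    sales
        Rows of (food_group, dollars, kg) -- one row per food/store record.
    method
        ``"pooled"`` (default): price = sum(dollars) / sum(kg), i.e. each
        food's price weighted by its sales volume.  ``"mean_of_ratios"``:
        unweighted mean of per-row prices, exposed for sensitivity analyses.

    Returns
    -------
    DataFrame with columns ``food_group, price_per_kg, provenance,
    yield_factor, total_kg``.  Groups absent from the sales table are simply
    absent (fill them with :func:`fill_missing_prices`).
    """
    if method not in ("pooled", "mean_of_ratios"):
        raise ValueError(f"unknown method {method!r}")
    required = {"food_group", "dollars", "kg"}
    if not required.issubset(sales.columns):
        raise ValueError(f"sales table needs columns {sorted(required)}")
    bad = sales.index[(sales["kg"] <= 0) | (sales["dollars"] < 0)]
    if len(bad):
        raise ValueError(
            f"sales rows with kg <= 0 or dollars < 0 at index {list(bad[:10])}"
        )
    grouped = sales.groupby("food_group", sort=True)
    if method == "pooled":
        price = grouped["dollars"].sum() / grouped["kg"].sum()
    else:
        price = grouped.apply(
            lambda g: float(np.mean(g["dollars"] / g["kg"])), include_groups=False
        )
    table = pd.DataFrame(
        {
            "food_group": price.index,
            "price_per_kg": price.values,
            "provenance": "observed",
            "yield_factor": 1.0,
            "total_kg": grouped["kg"].sum().values,
        }
    ).reset_index(drop=True)
    return table


def apply_yield(price_table: pd.DataFrame, yield_factors: dict | None) -> pd.DataFrame:
    """Convert purchased prices to edible prices.

    ``price_edible = price_purchased / yield_factor``: a yield below 1 means
    material loss (trimming, moisture), above 1 a cooking gain.  Groups not
    listed keep yield 1.0.
    """
    out = price_table.copy()
    if not yield_factors:
        return out
    for group, y in yield_factors.items():
        if y <= 0:
            raise ValueError(f"yield factor for {group!r} must be positive")
    y = out["food_group"].map(yield_factors).fillna(1.0)
    out["price_per_kg"] = out["price_per_kg"] / y
    out["yield_factor"] = y
    return out


def fill_missing_prices(
    price_table: pd.DataFrame,
    all_groups,
    categories: dict | None = None,
    manual_prices: dict | None = None,
    referenced_groups=None,
) -> pd.DataFrame:
    """Price food groups missing from the sales data via an ordered fallback.

    For each group in ``all_groups`` without an observed price, the first
    applicable rule fires:

    1. ``fallback:category_mean`` -- arithmetic mean of observed sibling
       prices in the same parent category (``categories`` maps group ->
       category);
    2. ``fallback:manual`` -- a user-supplied price;
    3. ``fallback:global_mean`` -- the global sales-weighted mean price.

    A group still priceless after all rules is allowed only if it is not in
    ``referenced_groups`` (groups actually appearing in recall data);
    otherwise a ``ValueError`` lists the offending groups.
    """
    categories = categories or {}
    manual_prices = manual_prices or {}
    out = price_table.copy()
    observed = out.set_index("food_group")
    rows = []
    unpriced = []
    global_mean = (
        float(
            np.sum(observed["price_per_kg"] * observed["total_kg"])
            / np.sum(observed["total_kg"])
        )
        if len(observed) and observed["total_kg"].sum() > 0
        else None
    )
    for group in all_groups:
        if group in observed.index:
            continue
        cat = categories.get(group)
        siblings = [
            g
            for g, c in categories.items()
            if c == cat and g != group and g in observed.index
        ]
        if cat is not None and siblings:
            price = float(observed.loc[siblings, "price_per_kg"].mean())
            prov = "fallback:category_mean"
        elif group in manual_prices:
            price = float(manual_prices[group])
            prov = "fallback:manual"
        elif global_mean is not None:
            price = global_mean
            prov = "fallback:global_mean"
        else:
            unpriced.append(group)
            continue
        logger.info("price fallback for %s: %s -> %.4f $/kg", group, prov, price)
        rows.append(
            {
                "food_group": group,
                "price_per_kg": price,
                "provenance": prov,
                "yield_factor": 1.0,
                "total_kg": 0.0,
            }
        )
    if referenced_groups is not None:
        still_bad = sorted(set(unpriced) & set(referenced_groups))
        if still_bad:
            raise ValueError(
                f"no price could be derived for recalled food group(s): {still_bad}"
            )
    for g in unpriced:
        logger.warning("food group %s left unpriced (not referenced by recalls)", g)
    if rows:
        out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
    return out


def cost_recalls(recalls: pd.DataFrame, price_table: pd.DataFrame) -> pd.DataFrame:
    """Convert recall records into one daily diet cost per participant-day.

    cost = sum over the day's records of amount_kg * price_per_kg; daily
    energy (kcal) is carried through by summation.
    """
    prices = price_table.set_index("food_group")["price_per_kg"]
    missing = sorted(set(recalls["food_group"]) - set(prices.index))
    if missing:
        raise KeyError(f"recalled food group(s) without a price: {missing}")
    rec = recalls.copy()
    rec["cost"] = rec["amount_kg"] * rec["food_group"].map(prices)
    daily = (
        rec.groupby(["participant_id", "recall_index"], sort=True)
        .agg(cost=("cost", "sum"), energy_kcal=("energy_kcal", "sum"))
        .reset_index()
    )
    return daily


def energy_adjusted_cost(
    daily_costs: pd.DataFrame,
    weights: pd.Series | None = None,
    reference_kcal: float = 2500.0,
) -> pd.DataFrame:
    """Per-person mean diet cost standardized to ``reference_kcal``.

    Each recall day's cost is rescaled by ``reference_kcal / energy`` and
    days are averaged within person.  Intended for descriptive tables only;
    regression analyses adjust for energy as a covariate instead.

    Returns a per-person frame (participant_id, cost_adj) with a weighted
    population mean in ``.attrs["weighted_mean"]`` when weights are given.
    """
    d = daily_costs.copy()
    if (d["energy_kcal"] <= 0).any():
        raise ValueError("energy must be positive for energy adjustment")
    d["cost_adj"] = d["cost"] * reference_kcal / d["energy_kcal"]
    per_person = d.groupby("participant_id")["cost_adj"].mean().reset_index()
    if weights is not None:
        w = per_person["participant_id"].map(weights)
        per_person.attrs["weighted_mean"] = float(
            np.sum(per_person["cost_adj"] * w) / np.sum(w)
        )
    return per_person
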