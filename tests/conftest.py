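"""Shared fixtures.

The two expensive computations -- the measurement-error recovery
experiment and the end-to-end study run -- are session-scoped so the
unit and acceptance tests share one fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dietcost import measurement_error as me
from dietcost import pipeline, price_engine
from dietcost import synthetic_data as synth


def recovery_food_specs():
    """One episodic + two daily food groups with known parameters."""
    return [
        synth.FoodGroupSpec(
            "veg_like", True, 0.20, 0.40, 0.50, 350, 7.0,
            p_consumer=1.0, p_day_given_consumer=0.7, factor_loading=0.5,
        ),
        synth.FoodGroupSpec(
            "grain_like", False, 0.15, 0.35, 0.45, 2800, 3.0, factor_loading=-0.4
        ),
        synth.FoodGroupSpec(
            "dairy_like", False, 0.25, 0.40, 0.45, 650, 4.0, factor_loading=0.1
        ),
    ]


@pytest.fixture(scope="session")
def recovery_bundle():
    """Fitted measurement-error model on the known-truth recovery cohort.

    n=500 participants, 3 recalls, 1 episodic + 2 daily foods, truthful
    reporting (the person-level reporting bias is a deliberate distortion
    for the plausibility screen and is inseparable from true
    between-person variation for any usual-intake method).
    """
    specs = recovery_food_specs()
    cc = synth.CohortConfig(
        n_participants=500, seed=42, food_specs=specs,
        missing_income_frac=0.0, missing_education_frac=0.0,
        under_reporter_frac=0.0, over_reporter_frac=0.0,
    )
    cohort, truth = synth.generate_cohort(cc)
    recalls = synth.generate_recalls(cohort, truth, cc)
    sales = synth.generate_sales_db(specs, dispersion=0.0, seed=1)
    daily = price_engine.cost_recalls(recalls, price_engine.build_price_table(sales))
    wide = me.recalls_to_wide(recalls, daily)
    spec = me.MEModelSpec(
        episodic_vars=["veg_like"],
        daily_vars=["dairy_like", "grain_like", "energy", "cost"],
        n_iter=2500, n_burn=1250, thin=2, seed=5, n_pseudo=100,
    )
    fitted = me.fit(spec, wide, cohort)
    pseudo = me.simulate_usual(fitted, cohort, seed=9)
    return {
        "cohort": cohort,
        "truth": truth,
        "recalls": recalls,
        "daily_costs": daily,
        "wide": wide,
        "fitted": fitted,
        "pseudo": pseudo,
    }


@pytest.fixture(scope="session")
def study_results():
    """Full pipeline run at test scale (n=500, n_pseudo=100, B=50)."""
    cfg = pipeline.StudyConfig(
        n_participants=500, seed=11, n_pseudo=100,
        n_iter=2500, n_burn=1250, thin=2, n_boot=50,
    )
    return pipeline.run_study(cfg)


@pytest.fixture()
def small_cohort():
    cc = synth.CohortConfig(n_participants=120, seed=3)
    cohort, truth = synth.generate_cohort(cc)
    return cc, cohort, truth
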