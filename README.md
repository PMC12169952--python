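# dietcost

Does eating closer to the EAT-Lancet reference diet cost more?
`dietcost` is an analysis pipeline for answering that question from
repeated 24-h dietary recalls linked to a retail food-price database,
built for nutrition epidemiologists who need the full chain — pricing,
diet-quality scoring, measurement-error correction and dose–response
regression — as tested, reusable components rather than a one-off
script stack.

The chain:

* **Sales-weighted pricing** — a food group's consumer price is
  Σ dollars / Σ kg over foods and stores (volume-weighted by
  construction), adjusted for preparation yield, with an ordered
  fallback hierarchy for groups missing from the sales data; recall
  days become daily diet costs ($CAD/d).
* **EAT-Lancet dietary index (EAT-I)** — a continuous 0–80 score with
  ten components (adequacy, moderation and optional "in-range" curves),
  defined declaratively in YAML; population means by the
  ratio-of-means (population ratio) method.
* **Usual intakes** — a multivariate two-part mixed model (probit
  consumption part + Box–Cox amount part per episodic food, amount
  parts for daily variables including energy and cost) fitted by MCMC
  with data augmentation, followed by Monte Carlo simulation of
  pseudo-individuals, removing within-person day-to-day error the way a
  single recall day never can.
* **Spline regression** — weighted least squares of usual cost on a
  restricted cubic spline of the score, with and without energy
  adjustment; the effect size is Δ = fitted cost at the 75th minus the
  25th weighted score percentile, with participant-bootstrap CIs and
  sociodemographic subgroup analyses.
* **Synthetic cohort generator** — a fully seeded study simulator
  (stratified sampling with balancing weights, episodic foods,
  reporting bias, a sales database) with known ground truth, so the
  whole pipeline is testable end to end.
* **Plausibility screen** — Huang-style comparison of reported energy
  with IOM predicted requirements (lightly active PAL), reported as a
  diagnostic.

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the whole study on a synthetic cohort at test scale:

```python
from dietcost import pipeline

cfg = pipeline.StudyConfig(
    n_participants=500, seed=11, n_pseudo=100,
    n_iter=2500, n_burn=1250, thin=2, n_boot=50,
)
res = pipeline.run_study(cfg)
print(res["overall_contrasts"][["energy_adjusted", "delta_cost", "ci_low", "ci_high"]])
oc = res["oracle_contrast"]
print(f"oracle: {oc.delta_cost:.2f} ({oc.ci_low:.2f}, {oc.ci_high:.2f})")
print(res["mean_eat_i"]["mean"], res["plausibility_summary"])
```

prints (about two minutes on one CPU):

```
 energy_adjusted  delta_cost   ci_low  ci_high
           False        1.36     1.07     1.65
            True        1.17     1.00     1.34
oracle: 1.12 (0.83, 1.40)
mean EAT-I 50.5 (95% CI 49.9, 51.1)
plausibility: under 15.5%, plausible 61.3%, over 23.1%
```

Reading this: moving from low (P25) to high (P75) adherence raises the
usual daily diet cost by an estimated 1.17 $CAD/d at fixed energy
(95 % CI 1.00–1.34).  The generator's known truth gives 1.12 $CAD/d —
the pipeline recovers it from noisy recalls within its CI.  Component
contrasts (`res["component_contrasts"]`) show the increase is driven by
the vegetables, fruits, fish & plant-protein and free-sugars
components, while the poultry & eggs component runs the other way
(−0.87 $CAD/d): in this population, diets adhering to that in-range
component are cheaper.  The plausibility split reflects the injected
20 %/15 % under/over-reporters blurred by day-to-day noise.

The same stages are available from the shell:

```bash
dietcost simulate --out run/        # cohort, truth, recalls, sales
dietcost prices   --out run/        # price table + daily costs
dietcost usual    --out run/        # measurement-error fit + pseudo-population
dietcost score    --out run/        # EAT-I scores per pseudo-individual
dietcost regress  --out run/        # P75-P25 contrasts
dietcost run      --out run/        # everything, one config
```

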