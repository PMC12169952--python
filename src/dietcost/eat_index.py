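"""EAT-Lancet dietary index (EAT-I) scoring.

The EAT-I measures alignment of a diet with the EAT-Lancet reference
dietary pattern on a continuous 0-80 point scale.  It has ten main
components of three kinds:

* **adequacy** -- more is better: points rise linearly from 0 at zero
  intake to the maximum at the reference target and plateau there;
* **moderation** -- less is better: full points at or below the target,
  declining linearly to zero at an upper cut-off;
* **optional** -- in-range is best: full points inside a plateau range,
  declining linearly to zero at outer cut-offs.

Six components carry 10 points and four (dairy, red & processed meats,
poultry & eggs, fish & plant-based proteins) carry 5, for a maximum of
80.  Components may be split into subcomponents (e.g. fish, legumes and
nuts) whose points sum to the component maximum.

Scoring rules are declarative: a YAML file lists each component's kind,
points, cut-offs and the intake variables (g/d) that feed it, so the
engine hard-codes nothing.  By default intakes are standardized to a
2500 kcal/d energy density before scoring, matching the reference-diet
convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ComponentSpec",
    "EatISpec",
    "default_eat_i_spec",
    "load_spec",
    "standardize_intake",
    "score_component",
    "score_total",
    "population_ratio_mean",
]

MAX_SCORE = 80.0


@dataclass
class ComponentSpec:
    """Declarative scoring rule for one EAT-I component or subcomponent."""

    name: str
    kind: str  # adequacy | moderation | optional
    max_points: float
    target: float | None = None  # adequacy target / moderation full-score bound
    upper: float | None = None  # moderation zero cut-off
    plateau_low: float | None = None  # optional: full-score range
    plateau_high: float | None = None
    zero_low: float | None = None  # optional: zero cut-offs
    zero_high: float | None = None
    mapping: dict[str, float] = field(default_factory=dict)
    subcomponents: list["ComponentSpec"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("adequacy", "moderation", "optional"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.subcomponents:
            total = sum(s.max_points for s in self.subcomponents)
            if abs(total - self.max_points) > 1e-9:
                raise ValueError(
                    f"{self.name}: subcomponent points sum to {total}, "
                    f"expected {self.max_points}"
                )
        elif self.kind == "adequacy":
            if self.target is None or self.target <= 0:
                raise ValueError(f"{self.name}: adequacy needs a positive target")
        elif self.kind == "moderation":
            if self.target is None or self.upper is None or self.upper <= self.target:
                raise ValueError(f"{self.name}: moderation needs target < upper")
        else:
            bounds = (self.zero_low, self.plateau_low, self.plateau_high, self.zero_high)
            if any(b is None for b in bounds):
                raise ValueError(f"{self.name}: optional needs all four cut-offs")
            if not (bounds[0] <= bounds[1] <= bounds[2] <= bounds[3]):
                raise ValueError(f"{self.name}: optional cut-offs out of order")

    def mapped_intake(self, intakes: pd.DataFrame | dict) -> np.ndarray:
        """Linear combination of intake variables feeding this component (g/d)."""
        if isinstance(intakes, dict):
            intakes = pd.DataFrame({k: np.atleast_1d(v) for k, v in intakes.items()})
        missing = [v for v in self.mapping if v not in intakes.columns]
        if missing:
            raise KeyError(
                f"component {self.name!r}: intake variable(s) {missing} not found"
            )
        out = np.zeros(len(intakes))
        for var, coef in self.mapping.items():
            out = out + coef * np.asarray(intakes[var], dtype=float)
        return out


@dataclass
class EatISpec:
    components: list[ComponentSpec]
    reference_kcal: float = 2500.0
    standardize_energy: bool = True

    @property
    def max_total(self) -> float:
        return sum(c.max_points for c in self.components)


def _component_from_dict(d: dict) -> ComponentSpec:
    subs = [_component_from_dict(s) for s in d.get("subcomponents", [])]
    keys = (
        "name",
        "kind",
        "max_points",
        "target",
        "upper",
        "plateau_low",
        "plateau_high",
        "zero_low",
        "zero_high",
        "mapping",
    )
    kwargs = {k: d[k] for k in keys if k in d}
    return ComponentSpec(subcomponents=subs, **kwargs)


def load_spec(path_or_stream) -> EatISpec:
    """Load a component specification from YAML."""
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    comps = [_component_from_dict(c) for c in raw["components"]]
    return EatISpec(
        components=comps,
        reference_kcal=float(raw.get("reference_kcal", 2500.0)),
        standardize_energy=bool(raw.get("standardize_energy", True)),
    )


def default_eat_i_spec() -> EatISpec:
    """The default ten-component EAT-I specification shipped with the package."""
    ref = importlib.resources.files("dietcost.data").joinpath("eat_i_default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_spec(fh)


def standardize_intake(
    intake: np.ndarray, energy: np.ndarray, reference_kcal: float = 2500.0
) -> np.ndarray:
    """Convert an absolute intake to a density per ``reference_kcal`` of energy."""
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive for density standardization")
    return np.asarray(intake, dtype=float) * reference_kcal / energy


def score_component(density_intake, spec: ComponentSpec) -> np.ndarray:
    """Score one component from its mapped intake (g/d per reference energy).

    Subcomponents are scored independently and summed.
    """
    x = np.asarray(density_intake, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"component {spec.name!r}: negative intake")
    if spec.subcomponents:
        raise ValueError("score_component operates on leaf specs; use score_total")
    m = spec.max_points
    if spec.kind == "adequacy":
        return m * np.minimum(x / spec.target, 1.0)
    if spec.kind == "moderation":
        pts = m * (spec.upper - x) / (spec.upper - spec.target)
        return np.clip(np.where(x <= spec.target, m, pts), 0.0, m)
    # optional: plateau with linear shoulders
    pts = np.full_like(x, m)
    if spec.plateau_low > spec.zero_low:
        left = m * (x - spec.zero_low) / (spec.plateau_low - spec.zero_low)
        pts = np.where(x < spec.plateau_low, left, pts)
    else:
        pts = np.where(x < spec.plateau_low, 0.0, pts)
    if spec.zero_high > spec.plateau_high:
        right = m * (spec.zero_high - x) / (spec.zero_high - spec.plateau_high)
        pts = np.where(x > spec.plateau_high, right, pts)
    else:
        pts = np.where(x > spec.plateau_high, 0.0, pts)
    return np.clip(pts, 0.0, m)


def _score_leaf(
    intakes: pd.DataFrame, energy: np.ndarray, spec: ComponentSpec, eat: EatISpec
) -> np.ndarray:
    x = spec.mapped_intake(intakes)
    if eat.standardize_energy:
        x = standardize_intake(x, energy, eat.reference_kcal)
    return score_component(x, spec)


def score_total(
    intakes: pd.DataFrame | dict,
    energy,
    spec: EatISpec | None = None,
) -> pd.DataFrame:
    """Score diets against the EAT-I.

    Parameters
    ----------
    intakes
        One row per diet; columns are intake variables in the units the
        component mapping expects (the default mapping takes kg/d food-group
        intakes and converts to g/d internally).
    energy
        Daily energy intake, kcal/d (scalar or one value per row).
    spec
        Component specification; the packaged default when omitted.

    Returns
    -------
    DataFrame with one column per main component plus ``total``.
    """
    if spec is None:
        spec = default_eat_i_spec()
    if isinstance(intakes, dict):
        intakes = pd.DataFrame({k: np.atleast_1d(v) for k, v in intakes.items()})
    energy = np.broadcast_to(np.asarray(energy, dtype=float), (len(intakes),))
    out = {}
    for comp in spec.components:
        if comp.subcomponents:
            pts = sum(_score_leaf(intakes, energy, s, spec) for s in comp.subcomponents)
        else:
            pts = _score_leaf(intakes, energy, comp, spec)
        out[comp.name] = pts
    scores = pd.DataFrame(out, index=intakes.index)
    scores["total"] = scores.sum(axis=1)
    return scores


def population_ratio_mean(
    intakes: pd.DataFrame,
    energy,
    weights,
    spec: EatISpec | None = None,
    participant_ids=None,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Population mean EAT-I score by the ratio-of-means method.

    The population score is ``score_total`` applied to the weighted mean
    intake (and energy) vector -- the mean diet is scored, rather than
    individual scores averaged, which differs whenever the scoring curve is
    nonlinear.  The bootstrap resamples participants (pseudo-individuals
    travel with their participant) and re-applies the ratio method.

    Returns a dict with ``mean``, ``ci_low``, ``ci_high``, ``se``,
    ``mean_of_scores`` (the naive average of individual scores, as a
    diagnostic) and ``n_boot``.
    """
    if spec is None:
        spec = default_eat_i_spec()
    w = np.asarray(weights, dtype=float)
    energy = np.broadcast_to(np.asarray(energy, dtype=float), (len(intakes),))
    if participant_ids is None:
        participant_ids = np.arange(len(intakes))
    pid = np.asarray(participant_ids)

    def ratio_score(mult: np.ndarray) -> float:
        ww = w * mult
        mean_intake = intakes.mul(ww, axis=0).sum() / ww.sum()
        mean_energy = float(np.sum(ww * energy) / ww.sum())
        return float(
            score_total(mean_intake.to_frame().T, mean_energy, spec)["total"].iloc[0]
        )

    point = ratio_score(np.ones(len(intakes)))
    indiv = score_total(intakes, energy, spec)["total"]
    mean_of_scores = float(np.sum(w * indiv) / w.sum())

    uniq = np.unique(pid)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        counts = np.bincount(
            rng.integers(0, len(uniq), size=len(uniq)), minlength=len(uniq)
        )
        mult = counts[np.searchsorted(uniq, pid)]
        boots[b] = ratio_score(mult.astype(float))
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else 0.0
    return {
        "mean": point,
        "se": se,
        "ci_low": point - 1.96 * se,
        "ci_high": point + 1.96 * se,
        "mean_of_scores": mean_of_scores,
        "n_boot": n_boot,
    }
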