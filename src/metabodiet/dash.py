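"""Quintile-based DASH (Dietary Approaches to Stop Hypertension) scoring.

Each of eight food-group components is scored 1-5 by the quintile of the
person's intake within the scored cohort (or against explicit cutoffs):
beneficial components (fruits, vegetables, nuts/legumes, whole grains,
low-fat dairy) score the quintile index directly, adverse components
(sodium, red/processed meat, sweetened beverages) score 6 minus it.  Totals
therefore range 8-40; higher means closer to the DASH dietary pattern.
Cohorts can then be stratified into percentile bands (e.g. bottom decile,
middle decile, top decile) of the total score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import substream

__all__ = [
    "DashConfig",
    "DashRecord",
    "dash_score",
    "score_cohort",
    "stratify_percentiles",
    "simulate_intakes",
    "DEFAULT_COMPONENTS",
    "DIET_INTAKE_TEMPLATES",
]

#: Fung-style 8-component DASH index: (component, direction).
DEFAULT_COMPONENTS = (
    ("fruits", "beneficial"),
    ("vegetables", "beneficial"),
    ("nuts_legumes", "beneficial"),
    ("whole_grains", "beneficial"),
    ("low_fat_dairy", "beneficial"),
    ("sodium", "adverse"),
    ("red_processed_meat", "adverse"),
    ("sweetened_beverages", "adverse"),
)


@dataclass
class DashConfig:
    """Component list with directions and optional explicit quintile cutoffs.

    ``quintile_cutoffs[name]`` is a list of 4 ascending thresholds, or None
    to derive them from the scored cohort (type-7 quantiles at
    20/40/60/80%).
    """

    components: tuple = DEFAULT_COMPONENTS
    quintile_cutoffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, direction in self.components:
            if direction not in ("beneficial", "adverse"):
                raise ValueError(f"{name}: unknown direction {direction}")
            cuts = self.quintile_cutoffs.get(name)
            if cuts is not None:
                cuts = list(cuts)
                if len(cuts) != 4 or any(
                    b <= a for a, b in zip(cuts, cuts[1:])
                ):
                    raise ValueError(
                        f"{name}: quintile cutoffs must be 4 strictly "
                        f"ascending values"
                    )


@dataclass
class DashRecord:
    person_id: str
    intakes: dict
    points: dict
    total: int
    percentile_band: str | None = None


def _quintile_index(value: float, cutoffs) -> int:
    """1 + number of cutoffs strictly below the value (ties fall low)."""
    return 1 + int(sum(c < value for c in cutoffs))


def dash_score(intakes: dict, config: DashConfig, person_id: str = "") -> DashRecord:
    """Score one person's component intakes against explicit cutoffs."""
    points = {}
    for name, direction in config.components:
        if name not in intakes:
            raise KeyError(f"missing component intake: {name}")
        cuts = config.quintile_cutoffs.get(name)
        if cuts is None:
            raise ValueError(
                f"{name}: no cutoffs; use score_cohort for from-cohort quintiles"
            )
        quint = _quintile_index(float(intakes[name]), cuts)
        points[name] = quint if direction == "beneficial" else 6 - quint
    return DashRecord(
        person_id=person_id,
        intakes={k: float(intakes[k]) for k, _ in config.components},
        points=points,
        total=int(sum(points.values())),
    )


def score_cohort(
    intake_table: pd.DataFrame, config: DashConfig | None = None
) -> list[DashRecord]:
    """Score a cohort (rows = persons, columns = components).

    Components without explicit cutoffs get from-cohort quintile cutoffs
    (type-7 quantiles at the 20/40/60/80th percentiles of the cohort).
    """
    config = config or DashConfig()
    cutoffs = dict(config.quintile_cutoffs)
    for name, _ in config.components:
        if name not in intake_table.columns:
            raise KeyError(f"missing component column: {name}")
        if cutoffs.get(name) is None:
            cuts = np.quantile(
                intake_table[name].to_numpy(dtype=float), [0.2, 0.4, 0.6, 0.8]
            )
            # strictly-ascending guard for near-constant cohorts
            eps = 1e-12 * max(1.0, float(np.abs(cuts).max()))
            for i in range(1, 4):
                if cuts[i] <= cuts[i - 1]:
                    cuts[i] = cuts[i - 1] + eps
            cutoffs[name] = list(cuts)
    resolved = DashConfig(components=config.components, quintile_cutoffs=cutoffs)
    return [
        dash_score(row.to_dict(), resolved, person_id=str(pid))
        for pid, row in intake_table.iterrows()
    ]


def stratify_percentiles(scores, bands) -> list[str | None]:
    """Assign each score to a closed percentile band, or None if outside all.

    Percentile rank uses the mid-rank convention ``100 * (rank - 0.5) / n``
    with tied scores sharing their mean rank.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    bands = [tuple(b) for b in bands]
    for lo, hi in bands:
        if not (0 <= lo <= hi <= 100):
            raise ValueError(f"band ({lo}, {hi}) outside [0, 100]")
    for i, (lo1, hi1) in enumerate(bands):
        for lo2, hi2 in bands[i + 1:]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValueError(
                    f"overlapping bands ({lo1}, {hi1}) and ({lo2}, {hi2})"
                )
    ranks = rankdata(scores, method="average")
    pct = 100.0 * (ranks - 0.5) / scores.size
    labels: list[str | None] = []
    for v in pct:
        label = None
        for lo, hi in bands:
            if lo <= v <= hi:
                label = f"{lo:g}-{hi:g}"
                break
        labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# Synthetic food-group intakes
# ---------------------------------------------------------------------------

#: Mean daily component intakes per diet template, graded from the
#: guideline-concordant diet 1 (fruit/veg-rich, low sodium/meat/sugar) to
#: the discordant diet 4.  Units: servings/day except sodium (mg/day).
DIET_INTAKE_TEMPLATES = {
    1: dict(fruits=4.5, vegetables=5.0, nuts_legumes=1.5, whole_grains=3.5,
            low_fat_dairy=2.5, sodium=2300, red_processed_meat=0.3,
            sweetened_beverages=0.1),
    2: dict(fruits=3.0, vegetables=3.5, nuts_legumes=1.0, whole_grains=2.5,
            low_fat_dairy=2.0, sodium=2600, red_processed_meat=0.8,
            sweetened_beverages=0.5),
    3: dict(fruits=1.5, vegetables=2.0, nuts_legumes=0.5, whole_grains=1.5,
            low_fat_dairy=1.2, sodium=3200, red_processed_meat=1.5,
            sweetened_beverages=1.2),
    4: dict(fruits=0.7, vegetables=1.0, nuts_legumes=0.2, whole_grains=0.7,
            low_fat_dairy=0.8, sodium=3600, red_processed_meat=2.5,
            sweetened_beverages=2.5),
}


def simulate_intakes(
    n_per_template: int = 19,
    templates: dict | None = None,
    intake_cv: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal per-person intakes around each diet template.

    Returns a DataFrame indexed by person id (``T<template>_P<i>``) with a
    ``template`` column plus one column per food-group component.
    """
    templates = templates or DIET_INTAKE_TEMPLATES
    sigma = float(np.sqrt(np.log1p(intake_cv**2)))
    rows = []
    for label, means in templates.items():
        for i in range(n_per_template):
            rng = substream(seed, "intake", label, i)
            row = {"person_id": f"T{label}_P{i + 1:02d}", "template": label}
            for comp, mu in means.items():
                row[comp] = float(mu * np.exp(rng.normal() * sigma))
            rows.append(row)
    return pd.DataFrame(rows).set_index("person_id")
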