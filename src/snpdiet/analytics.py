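"""Nutrient-adequacy and composition analytics for optimized rations.

Percent-of-guideline tables (one-decimal, half away from zero), color-coded
adequacy (separate threshold sets for hot cooked meals and take-home rations),
food-group weight allocation, radar ratios, and per-group nutrient/cost
contribution breakdowns.  All chart outputs are structured data; rendering is
a consumer concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .food_data import FoodDatabase, effective_nutrients_per_100g, effective_price_per_gram
from .guidelines import GuidelineSet
from .lp_engine import RationSolution
from .nutrients import NUTRIENT_FIELDS, NutrientVector

GREEN = "green"
ORANGE = "orange"
RED = "red"

#: (green strictly above, red strictly below); boundaries fall to orange.
COLOR_THRESHOLDS = {"hcm": (60.0, 30.0), "thr": (80.0, 50.0)}


class AnalyticsError(ValueError):
    pass


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (table-printing convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AdequacyRow:
    nutrient: str
    guideline: float
    content: float
    percent: float | None  # None when the guideline target is 0 (unconstrained)
    color: str | None = None

    def as_dict(self) -> dict:
        return {
            "nutrient": self.nutrient,
            "guideline": self.guideline,
            "content": self.content,
            "percent": self.percent,
            "color": self.color,
        }


def percent_of_guideline(
    content: NutrientVector, guidelines: GuidelineSet
) -> list[AdequacyRow]:
    """Per-nutrient percent of the guideline target, one-decimal rounded.

    Rows whose target is 0 are emitted with ``percent=None`` (undefined), not
    computed.
    """
    rows = []
    for nut in NUTRIENT_FIELDS:
        target = guidelines.targets[nut]
        value = content[nut]
        percent = round1(100.0 * value / target) if target > 0 else None
        rows.append(AdequacyRow(nutrient=nut, guideline=target, content=value, percent=percent))
    return rows


def adequacy_color(percent: float, mode: str) -> str:
    """Color-code an adequacy percentage.

    Hot-cooked-meal rule: green above 60%, red below 30%, orange between
    (inclusive).  Take-home-ration rule: green above 80%, red below 50%.
    """
    if mode not in COLOR_THRESHOLDS:
        raise AnalyticsError(f"unknown mode {mode!r}; expected 'hcm' or 'thr'")
    if percent < 0:
        raise AnalyticsError("percent must be >= 0")
    green_above, red_below = COLOR_THRESHOLDS[mode]
    if percent > green_above:
        return GREEN
    if percent < red_below:
        return RED
    return ORANGE


def adequacy_table(
    content: NutrientVector, guidelines: GuidelineSet, mode: str
) -> list[AdequacyRow]:
    """percent_of_guideline with colors attached (skipping undefined rows)."""
    rows = percent_of_guideline(content, guidelines)
    return [
        AdequacyRow(
            r.nutrient,
            r.guideline,
            r.content,
            r.percent,
            adequacy_color(r.percent, mode) if r.percent is not None else None,
        )
        for r in rows
    ]


# ---------------------------------------------------------------------------
# Composition breakdowns

def _per_item_profile(
    item_id: str,
    quantity: float,
    db: FoodDatabase,
    use_subsidy: bool,
    apply_fortification: bool,
) -> list[tuple[str, float, NutrientVector, float]]:
    """Decompose one solution item into (group, grams, nutrients, cost) parts.

    Raw foods map directly; recipes (quantity = serving multiplier) decompose
    into their ingredients' food groups.
    """
    if item_id in db.foods:
        food = db.foods[item_id]
        per_g = effective_nutrients_per_100g(food, apply_fortification) * 0.01
        return [
            (
                food.group.value,
                quantity,
                per_g * quantity,
                quantity * effective_price_per_gram(food, use_subsidy),
            )
        ]
    if item_id in db.recipes:
        parts = []
        for food_id, grams in db.recipes[item_id].ingredients:
            food = db.foods[food_id]
            g = grams * quantity
            per_g = effective_nutrients_per_100g(food, apply_fortification) * 0.01
            parts.append(
                (
                    food.group.value,
                    g,
                    per_g * g,
                    g * effective_price_per_gram(food, use_subsidy),
                )
            )
        return parts
    raise AnalyticsError(f"solution item {item_id!r} is neither a food nor a recipe")


def food_group_allocation(
    solution: RationSolution,
    db: FoodDatabase,
    use_subsidy: bool = False,
    apply_fortification: bool = True,
) -> dict[str, float]:
    """Share of total raw weight per food group, in percent (sums to 100)."""
    weights: dict[str, float] = {}
    for item_id, q in solution.quantities.items():
        if q <= 0:
            continue
        for group, grams, _, _ in _per_item_profile(
            item_id, q, db, use_subsidy, apply_fortification
        ):
            weights[group] = weights.get(group, 0.0) + grams
    total = sum(weights.values())
    if total <= 0:
        raise AnalyticsError("zero-weight solution has no allocation")
    return {g: 100.0 * w / total for g, w in sorted(weights.items())}


def nutrient_ratio_radar(
    content: NutrientVector, guidelines: GuidelineSet
) -> dict[str, float | None]:
    """Unrounded content/target ratio per nutrient; 1.0 means target exactly
    met.  Zero-target nutrients map to None (flagged, not computed)."""
    out: dict[str, float | None] = {}
    for nut in NUTRIENT_FIELDS:
        target = guidelines.targets[nut]
        out[nut] = (content[nut] / target) if target > 0 else None
    return out


def contribution_breakdown(
    solution: RationSolution,
    db: FoodDatabase,
    use_subsidy: bool = False,
    apply_fortification: bool = True,
) -> dict:
    """Per-group nutrient contributions (absolute) and cost shares (percent).

    Group nutrient contributions sum to the solution totals; cost shares sum
    to 100% (all zero, with ``zero_cost`` flagged, for a free solution).
    """
    nutrients: dict[str, dict[str, float]] = {}
    costs: dict[str, float] = {}
    for item_id, q in solution.quantities.items():
        if q <= 0:
            continue
        for group, _, nvec, cost in _per_item_profile(
            item_id, q, db, use_subsidy, apply_fortification
        ):
            bucket = nutrients.setdefault(group, {n: 0.0 for n in NUTRIENT_FIELDS})
            for n, v in nvec.as_dict().items():
                bucket[n] += v
            costs[group] = costs.get(group, 0.0) + cost
    total_cost = sum(costs.values())
    zero_cost = total_cost <= 0
    cost_shares = {
        g: (0.0 if zero_cost else 100.0 * c / total_cost) for g, c in sorted(costs.items())
    }
    return {
        "nutrient_contributions": {g: nutrients[g] for g in sorted(nutrients)},
        "cost_shares": cost_shares,
        "zero_cost": zero_cost,
    }
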