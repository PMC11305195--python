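"""Take-home-ration (THR) optimization: raw foods in grams per day.

Program rules encoded here: at least one selected food from each of the four
mandatory groups (cereals and millets, pulses and legumes, sugars, edible oils
and fats); macronutrient totals within guideline bands; micronutrients capped
by tolerable upper limits where given (and optionally enforced as lower
bounds); a consistent cereal:pulse mass ratio (default 2:1); per-item and
per-group quantity windows, with restricted item classes (oils, sugars/
jaggery, nuts and seeds, milk powder, egg) given tighter default windows; and
an optional compulsory cereal or millet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import analytics
from .food_data import (
    FoodDatabase,
    FoodGroup,
    effective_nutrients_per_100g,
    effective_price_per_gram,
)
from .guidelines import GuidelineSet
from .lp_engine import (
    CONTINUOUS_GRAMS,
    ConstraintSet,
    DecisionSpec,
    RationSolution,
    RatioConstraint,
    SolverConfig,
    enumerate_k_best,
)
from .nutrients import MACROS, NUTRIENT_FIELDS

MANDATORY_THR_GROUPS = (
    FoodGroup.CEREALS_AND_MILLETS,
    FoodGroup.PULSES_AND_LEGUMES,
    FoodGroup.SUGARS,
    FoodGroup.EDIBLE_OILS_AND_FATS,
)

#: Default per-item (min g, max g) windows when selected, by food group.
#: Restricted classes get tight windows; anything else gets the general window.
DEFAULT_GROUP_ITEM_WINDOWS: dict[FoodGroup, tuple[float, float]] = {
    FoodGroup.EDIBLE_OILS_AND_FATS: (5.0, 15.0),
    FoodGroup.SUGARS: (5.0, 30.0),
    FoodGroup.NUTS_AND_DRY_FRUITS: (5.0, 20.0),
    FoodGroup.MILK_AND_MILK_PRODUCTS: (5.0, 40.0),
    FoodGroup.EGG: (25.0, 50.0),
}
GENERAL_ITEM_WINDOW: tuple[float, float] = (5.0, 250.0)


class THRError(ValueError):
    pass


@dataclass
class THRConfig:
    """Run configuration for THR optimization (quantities in g/day)."""

    use_subsidy: bool = False
    apply_fortification: bool = True
    budget: float | None = 8.0
    budget_hard: bool = False
    cereal_pulse_ratio: float = 2.0
    ratio_tolerance: float = 0.02
    group_windows: dict[tuple[FoodGroup, str], tuple[float | None, float | None]] = field(
        default_factory=dict
    )
    item_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    must_include_food: str | None = None
    k_alternatives: int = 1
    enforce_micros: frozenset[str] = frozenset()
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if self.cereal_pulse_ratio <= 0:
            raise THRError("cereal_pulse_ratio must be > 0")
        for item, (lo, hi) in self.item_windows.items():
            if lo > hi:
                raise THRError(f"item window for {item!r}: min {lo} > max {hi}")


def item_window(food_id: str, group: FoodGroup, config: THRConfig) -> tuple[float, float]:
    if food_id in config.item_windows:
        return config.item_windows[food_id]
    return DEFAULT_GROUP_ITEM_WINDOWS.get(group, GENERAL_ITEM_WINDOW)


def build_thr_model(
    db: FoodDatabase, guidelines: GuidelineSet, config: THRConfig
) -> tuple[list[DecisionSpec], ConstraintSet]:
    """Decision variables (one per food, unit = 1 g) and the THR constraint set."""
    for group in MANDATORY_THR_GROUPS:
        if not db.foods_in_group(group):
            raise THRError(f"database has no food in mandatory group {group.value!r}")
    if config.must_include_food is not None:
        food = db.foods.get(config.must_include_food)
        if food is None:
            raise THRError(
                f"must_include_food {config.must_include_food!r} not in database"
            )
        if food.group is not FoodGroup.CEREALS_AND_MILLETS:
            raise THRError(
                f"must_include_food {config.must_include_food!r} is not a cereal or millet"
            )

    decisions = []
    for food in db.foods.values():
        per_g = effective_nutrients_per_100g(food, config.apply_fortification) * 0.01
        decisions.append(
            DecisionSpec(
                item_id=food.id,
                kind=CONTINUOUS_GRAMS,
                bounds=item_window(food.id, food.group, config),
                unit_cost=effective_price_per_gram(food, config.use_subsidy),
                unit_nutrients=per_g,
                unit_weight=1.0,
                group=food.group.value,
                mode="premix" if food.premix_eligible else "whole",
            )
        )

    nutrient_lower: dict[str, float] = {}
    nutrient_upper: dict[str, float] = {}
    for macro in MACROS:
        lo, hi = guidelines.macro_bounds(macro)
        if guidelines.targets[macro] > 0:
            nutrient_lower[macro] = lo
            nutrient_upper[macro] = hi
    for nut in config.enforce_micros:
        if guidelines.targets[nut] > 0:
            nutrient_lower[nut] = guidelines.targets[nut]
    if guidelines.upper_limits is not None:
        for nut in NUTRIENT_FIELDS:
            ul = guidelines.upper_limits[nut]
            if ul > 0:
                nutrient_upper[nut] = min(nutrient_upper.get(nut, ul), ul)

    constraints = ConstraintSet(
        nutrient_lower=nutrient_lower,
        nutrient_upper=nutrient_upper,
        group_min_count={g.value: 1 for g in MANDATORY_THR_GROUPS},
        quantity_windows={
            (g.value, mode): window for (g, mode), window in config.group_windows.items()
        },
        ratio_constraints=[
            RatioConstraint(
                name="cereal_to_pulse",
                numerator_groups=(FoodGroup.CEREALS_AND_MILLETS.value,),
                denominator_groups=(FoodGroup.PULSES_AND_LEGUMES.value,),
                ratio=config.cereal_pulse_ratio,
                tolerance=config.ratio_tolerance,
            )
        ],
        force_select=(config.must_include_food,) if config.must_include_food else (),
        budget=config.budget,
        budget_hard=config.budget_hard,
    )
    return decisions, constraints


def optimize_thr(
    db: FoodDatabase, guidelines: GuidelineSet, config: THRConfig | None = None
) -> list[RationSolution]:
    """Least-cost THR solutions, cheapest first, up to ``k_alternatives``."""
    config = config or THRConfig()
    decisions, constraints = build_thr_model(db, guidelines, config)
    solutions = enumerate_k_best(
        decisions, constraints, config.k_alternatives, config.solver
    )
    if not solutions:
        from .lp_engine import solve_min_cost

        return [solve_min_cost(decisions, constraints, config.solver)]
    return solutions


def thr_product_summary(solution: RationSolution, guidelines: GuidelineSet) -> dict:
    """Report: daily cost with weekly (x7), monthly (x30), yearly (x365)
    extrapolations, ingredient grams, and percent-of-guideline adequacy."""
    if not solution.feasible:
        raise THRError(f"cannot summarize a solution with status {solution.status!r}")
    cost = solution.total_cost
    return {
        "cost": {
            "daily": cost,
            "weekly": cost * 7,
            "monthly": cost * 30,
            "yearly": cost * 365,
        },
        "ingredient_grams": {
            fid: g for fid, g in sorted(solution.quantities.items()) if g > 0
        },
        "status": solution.status,
        "adequacy": [
            row.as_dict()
            for row in analytics.percent_of_guideline(solution.nutrient_totals, guidelines)
        ],
    }
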