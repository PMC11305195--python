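"""Hot-cooked-meal (HCM) optimization and weekly menu assembly.

A daily meal selects recipes by category (main dish, curry, side dish,
optional additional items) with semi-continuous serving multipliers: a chosen
recipe is served at between a configurable fraction of its predetermined
serving size (default 0.5) and 1.5 times it.  Compulsory recipes (egg / milk /
milk-powder items, chosen before optimization) are forced into the solution.
For severely-acutely-malnourished (SAM) beneficiary categories, whose targets
are higher, an accepted meal is augmented with 1-2 snacks and/or a bounded
uniform scale-up of all servings.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass, field

import numpy as np

from .food_data import FoodDatabase, Recipe, RecipeCategory, recipe_profile
from .guidelines import GuidelineSet
from .lp_engine import (
    OPTIMAL,
    SEMI_CONTINUOUS_SERVINGS,
    ConstraintSet,
    DecisionSpec,
    RationSolution,
    SolverConfig,
    enumerate_k_best,
    solve_min_cost,
)
from .nutrients import MACROS, NUTRIENT_FIELDS, NutrientVector

#: Atwater energy conversion factors (kcal per g).
ATWATER_PROTEIN = 4.0
ATWATER_FAT = 9.0

#: Pseudo-category under which compulsory recipes are counted (they are forced
#: in regardless of their nominal category, so they are exempt from counts).
COMPULSORY_LABEL = "compulsory"

DEFAULT_CATEGORY_COUNTS: dict[RecipeCategory, tuple[int, int]] = {
    RecipeCategory.MAIN_DISH: (1, 1),
    RecipeCategory.CURRY: (1, 1),
    RecipeCategory.SIDE_DISH: (0, 1),
    RecipeCategory.ADDITIONAL: (0, 2),
    RecipeCategory.SNACK: (0, 0),
}


class HCMError(ValueError):
    pass


@dataclass
class MealConfig:
    """Configuration for one day's HCM optimization."""

    category_counts: dict[RecipeCategory, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    serving_fraction_low: float = 0.5
    serving_fraction_high: float = 1.5
    compulsory_recipe_ids: tuple[str, ...] = ()
    budget: float | None = 8.0
    budget_hard: bool = False
    use_subsidy: bool = False
    apply_fortification: bool = True
    k_alternatives: int = 1
    sam_scale_cap: float = 1.25
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if not (0 < self.serving_fraction_low <= 1 <= self.serving_fraction_high):
            raise HCMError(
                "need 0 < serving_fraction_low <= 1 <= serving_fraction_high, got "
                f"({self.serving_fraction_low}, {self.serving_fraction_high})"
            )


def _macro_bounds(guidelines: GuidelineSet) -> tuple[dict[str, float], dict[str, float]]:
    lower, upper = {}, {}
    for macro in MACROS:
        if guidelines.targets[macro] > 0:
            lo, hi = guidelines.macro_bounds(macro)
            lower[macro] = lo
            upper[macro] = hi
    return lower, upper


def build_meal_model(
    db: FoodDatabase,
    guidelines: GuidelineSet,
    selection: list[str],
    config: MealConfig,
) -> tuple[list[DecisionSpec], ConstraintSet]:
    """Decisions (one per selected recipe, unit = 1 serving) and constraints."""
    if not selection:
        raise HCMError("recipe selection is empty")
    unknown = [rid for rid in selection if rid not in db.recipes]
    if unknown:
        raise HCMError(f"selection references unknown recipe id(s): {unknown}")
    missing_compulsory = [r for r in config.compulsory_recipe_ids if r not in db.recipes]
    if missing_compulsory:
        raise HCMError(f"compulsory recipe id(s) not in database: {missing_compulsory}")
    pool = list(dict.fromkeys(list(selection) + list(config.compulsory_recipe_ids)))
    compulsory = set(config.compulsory_recipe_ids)

    for category, (cmin, _cmax) in config.category_counts.items():
        if cmin > 0 and not any(
            db.recipes[rid].category is category and rid not in compulsory for rid in pool
        ):
            raise HCMError(
                f"no recipe of required category {category.value!r} in selection"
            )

    decisions = []
    for rid in pool:
        recipe = db.recipes[rid]
        nutrients, cost, weight = recipe_profile(
            recipe, db, config.use_subsidy, config.apply_fortification
        )
        label = COMPULSORY_LABEL if rid in compulsory else recipe.category.value
        decisions.append(
            DecisionSpec(
                item_id=rid,
                kind=SEMI_CONTINUOUS_SERVINGS,
                bounds=(config.serving_fraction_low, config.serving_fraction_high),
                unit_cost=cost,
                unit_nutrients=nutrients,
                unit_weight=weight,
                group=label,
            )
        )

    nutrient_lower, nutrient_upper = _macro_bounds(guidelines)
    if guidelines.upper_limits is not None:
        for nut in NUTRIENT_FIELDS:
            ul = guidelines.upper_limits[nut]
            if ul > 0:
                nutrient_upper[nut] = min(nutrient_upper.get(nut, ul), ul)
    constraints = ConstraintSet(
        nutrient_lower=nutrient_lower,
        nutrient_upper=nutrient_upper,
        group_min_count={
            cat.value: cmin for cat, (cmin, _) in config.category_counts.items() if cmin > 0
        },
        group_max_count={
            cat.value: cmax for cat, (_, cmax) in config.category_counts.items()
        },
        force_select=tuple(sorted(compulsory)),
        budget=config.budget,
        budget_hard=config.budget_hard,
    )
    return decisions, constraints


def optimize_meal(
    db: FoodDatabase,
    guidelines: GuidelineSet,
    selection: list[str],
    config: MealConfig | None = None,
) -> list[RationSolution]:
    """Least-cost daily meals from the selected recipes, cheapest first."""
    config = config or MealConfig()
    decisions, constraints = build_meal_model(db, guidelines, selection, config)
    solutions = enumerate_k_best(
        decisions, constraints, config.k_alternatives, config.solver
    )
    if not solutions:
        return [solve_min_cost(decisions, constraints, config.solver)]
    return solutions


# ---------------------------------------------------------------------------
# SAM augmentation

def augment_for_sam(
    solution: RationSolution,
    db: FoodDatabase,
    guidelines_sam: GuidelineSet,
    config: MealConfig | None = None,
) -> RationSolution:
    """Augment an accepted meal to meet elevated SAM macro targets.

    Searches, in order of preference, adding 1 snack, 2 snacks, scaling all
    serving multipliers uniformly (capped at ``sam_scale_cap`` and never past
    the serving-fraction ceiling), and snack+scale combinations; among
    configurations meeting all macro lower bounds the cheapest wins.  If none
    suffices the best-effort (highest-energy, then cheapest) configuration is
    returned with a per-nutrient shortfall report — never silently.
    """
    config = config or MealConfig()
    if not solution.feasible:
        raise HCMError("cannot augment an infeasible solution")
    lower, _upper = _macro_bounds(guidelines_sam)
    base_q = {rid: q for rid, q in solution.quantities.items() if q > 0}
    snack_pool = sorted(
        rid
        for rid, r in db.recipes.items()
        if r.category is RecipeCategory.SNACK and rid not in base_q
    )

    profiles: dict[str, tuple[NutrientVector, float]] = {}
    for rid in itertools.chain(base_q, snack_pool):
        nvec, cost, _w = recipe_profile(
            db.recipes[rid], db, config.use_subsidy, config.apply_fortification
        )
        profiles[rid] = (nvec, cost)

    scale_grid = [1.0] + [
        round(s, 4)
        for s in np.arange(1.05, config.sam_scale_cap + 1e-9, 0.05).tolist()
    ]
    snack_combos = (
        [()]
        + [(s,) for s in snack_pool]
        + [c for c in itertools.combinations(snack_pool, 2)]
    )

    def evaluate(combo, scale):
        q = {
            rid: min(m * scale, config.serving_fraction_high) for rid, m in base_q.items()
        }
        for rid in combo:
            q[rid] = 1.0
        totals = np.zeros(len(NUTRIENT_FIELDS))
        cost = 0.0
        for rid, m in q.items():
            nvec, c = profiles[rid]
            totals += m * nvec.values
            cost += m * c
        tv = NutrientVector(totals)
        short = {
            nut: lo - tv[nut] for nut, lo in lower.items() if tv[nut] < lo - 1e-9
        }
        return q, tv, cost, short

    best_ok = None  # (cost, n_snacks, q, totals)
    best_any = None  # (-energy, cost, q, totals, short)
    for combo in snack_combos:
        for scale in scale_grid:
            q, totals, cost, short = evaluate(combo, scale)
            if not short:
                key = (cost, len(combo))
                if best_ok is None or key < best_ok[0]:
                    best_ok = (key, q, totals, cost)
            key_any = (-totals["energy_kcal"], cost)
            if best_any is None or key_any < best_any[0]:
                best_any = (key_any, q, totals, cost, short)

    if best_ok is not None:
        _, q, totals, cost = best_ok
        best_effort = False
        shortfall: dict[str, float] = {}
    else:
        _, q, totals, cost, shortfall = best_any
        best_effort = True
    quantities = {rid: 0.0 for rid in solution.quantities}
    quantities.update(q)
    return RationSolution(
        quantities=quantities,
        selected={rid: v > 0 for rid, v in quantities.items()},
        total_cost=cost,
        nutrient_totals=totals,
        status=OPTIMAL if not best_effort else solution.status,
        best_effort=best_effort,
        shortfall=shortfall,
    )


# ---------------------------------------------------------------------------
# Weekly menus

@dataclass
class WeeklyMenu:
    """An ordered set of daily meal solutions with cost and macro statistics."""

    days: list[tuple[str, RationSolution]]
    mean_cost: float
    sd_cost: float
    macro_series: list[dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "days": [
                {"label": label, "solution": sol.to_dict()} for label, sol in self.days
            ],
            "mean_cost": self.mean_cost,
            "sd_cost": self.sd_cost,
            "macro_series": self.macro_series,
        }


def build_weekly_menu(
    day_solutions: list[RationSolution], labels: list[str] | None = None
) -> WeeklyMenu:
    """Assemble daily solutions into a weekly menu with summary statistics.

    Mean/SD of daily cost use the sample standard deviation (n-1 denominator;
    0.0 for a single day).  The macro series reports per-day energy, protein
    and fat together with protein:energy and fat:energy as percent of energy
    via Atwater factors (4 kcal/g protein, 9 kcal/g fat).
    """
    if not day_solutions:
        raise HCMError("weekly menu needs at least one day")
    if labels is None:
        labels = [f"day_{i + 1}" for i in range(len(day_solutions))]
    if len(labels) != len(day_solutions):
        raise HCMError("labels and day_solutions length mismatch")
    costs = [s.total_cost for s in day_solutions]
    mean_cost = statistics.fmean(costs)
    sd_cost = statistics.stdev(costs) if len(costs) > 1 else 0.0
    series = []
    for label, sol in zip(labels, day_solutions):
        energy = sol.nutrient_totals["energy_kcal"]
        protein = sol.nutrient_totals["protein_g"]
        fat = sol.nutrient_totals["fat_g"]
        series.append(
            {
                "label": label,
                "energy_kcal": energy,
                "protein_g": protein,
                "fat_g": fat,
                "protein_pct_energy": (
                    100.0 * ATWATER_PROTEIN * protein / energy if energy > 0 else math.nan
                ),
                "fat_pct_energy": (
                    100.0 * ATWATER_FAT * fat / energy if energy > 0 else math.nan
                ),
            }
        )
    return WeeklyMenu(
        days=list(zip(labels, day_solutions)),
        mean_cost=mean_cost,
        sd_cost=sd_cost,
        macro_series=series,
    )
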