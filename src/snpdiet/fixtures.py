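"""Deterministic synthetic food/recipe databases and hand-built toy instances.

Everything here is synthetic: nutrient densities are drawn from plausible
food-composition-table-like ranges per food group, and prices from plausible
per-kg retail ranges, but no real regional food list or market survey is
mimicked.  The generator is seeded and reproducible; feasibility labels are
never asserted without either solving (feasible mode) or an explicit
analytical certificate (infeasible mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .food_data import FoodDatabase, FoodGroup, FoodItem, Recipe, RecipeCategory
from .guidelines import BeneficiaryCategory, default_guidelines
from .nutrients import NutrientVector

GUARANTEED_FEASIBLE = "guaranteed_feasible"
GUARANTEED_INFEASIBLE = "guaranteed_infeasible"
UNCONSTRAINED = "unconstrained"


class FixtureError(RuntimeError):
    pass


# Plausible per-100 g nutrient ranges by group (synthetic, loosely modeled on
# composition-table magnitudes).  Unlisted nutrients are drawn near zero.
_GROUP_RANGES: dict[FoodGroup, dict[str, tuple[float, float]]] = {
    FoodGroup.CEREALS_AND_MILLETS: {
        "energy_kcal": (320, 360), "protein_g": (7, 12), "fat_g": (1, 4),
        "fiber_g": (2, 10), "calcium_mg": (10, 40), "iron_mg": (1, 5),
        "zinc_mg": (1, 3), "magnesium_mg": (40, 140), "folate_ug": (10, 40),
        "vitamin_b1_mg": (0.2, 0.5), "vitamin_b3_mg": (1, 4),
    },
    FoodGroup.PULSES_AND_LEGUMES: {
        "energy_kcal": (320, 350), "protein_g": (20, 25), "fat_g": (1, 6),
        "fiber_g": (8, 16), "calcium_mg": (40, 150), "iron_mg": (3, 8),
        "zinc_mg": (2, 4), "magnesium_mg": (100, 200), "folate_ug": (100, 400),
        "vitamin_b1_mg": (0.3, 0.6), "vitamin_b3_mg": (1, 3),
    },
    FoodGroup.SUGARS: {"energy_kcal": (380, 400)},
    FoodGroup.EDIBLE_OILS_AND_FATS: {"energy_kcal": (880, 900), "fat_g": (99, 100)},
    FoodGroup.MILK_AND_MILK_PRODUCTS: {
        "energy_kcal": (480, 510), "protein_g": (24, 27), "fat_g": (24, 28),
        "calcium_mg": (800, 1000), "vitamin_b2_mg": (1.0, 1.6),
        "vitamin_b12_ug": (1.5, 3.0), "zinc_mg": (3, 4),
    },
    FoodGroup.GREEN_LEAFY_VEGETABLES: {
        "energy_kcal": (20, 45), "protein_g": (2, 4), "fat_g": (0.2, 0.8),
        "fiber_g": (2, 4), "calcium_mg": (80, 300), "iron_mg": (1, 5),
        "folate_ug": (60, 150), "vitamin_a_ug": (150, 600), "vitamin_c_mg": (20, 60),
    },
    FoodGroup.EGG: {
        "energy_kcal": (140, 170), "protein_g": (12, 14), "fat_g": (9, 12),
        "vitamin_a_ug": (100, 200), "vitamin_b12_ug": (0.8, 1.2),
    },
    FoodGroup.ROOTS_AND_TUBERS: {
        "energy_kcal": (70, 110), "protein_g": (1, 2.5), "fat_g": (0.05, 0.3),
        "fiber_g": (1, 3), "vitamin_c_mg": (5, 20),
    },
}

_GROUP_PRICE_RANGES: dict[FoodGroup, tuple[float, float]] = {
    FoodGroup.CEREALS_AND_MILLETS: (2.5, 5.0),
    FoodGroup.PULSES_AND_LEGUMES: (6.0, 11.0),
    FoodGroup.SUGARS: (3.5, 5.0),
    FoodGroup.EDIBLE_OILS_AND_FATS: (10.0, 16.0),
    FoodGroup.MILK_AND_MILK_PRODUCTS: (20.0, 35.0),
    FoodGroup.GREEN_LEAFY_VEGETABLES: (3.0, 8.0),
    FoodGroup.EGG: (80.0, 120.0),
    FoodGroup.ROOTS_AND_TUBERS: (1.5, 4.0),
}

_DEFAULT_N_FOODS: dict[FoodGroup, int] = {
    FoodGroup.CEREALS_AND_MILLETS: 2,
    FoodGroup.PULSES_AND_LEGUMES: 2,
    FoodGroup.SUGARS: 1,
    FoodGroup.EDIBLE_OILS_AND_FATS: 1,
    FoodGroup.MILK_AND_MILK_PRODUCTS: 1,
    FoodGroup.GREEN_LEAFY_VEGETABLES: 1,
    FoodGroup.EGG: 1,
    FoodGroup.ROOTS_AND_TUBERS: 1,
}


@dataclass
class FixtureSpec:
    seed: int = 0
    n_foods_per_group: dict[FoodGroup, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_FOODS)
    )
    mode: str = GUARANTEED_FEASIBLE
    include_recipes: bool = True
    max_retries: int = 20

    def __post_init__(self):
        if self.mode not in (GUARANTEED_FEASIBLE, GUARANTEED_INFEASIBLE, UNCONSTRAINED):
            raise FixtureError(f"unknown feasibility mode {self.mode!r}")
        for g, n in self.n_foods_per_group.items():
            if n < 0:
                raise FixtureError(f"n_foods for {g.value}: must be >= 0")


def _draw_food(rng: np.random.Generator, group: FoodGroup, idx: int) -> FoodItem:
    ranges = _GROUP_RANGES.get(group, {})
    vals = {}
    for nut, (lo, hi) in ranges.items():
        vals[nut] = float(rng.uniform(lo, hi))
    plo, phi = _GROUP_PRICE_RANGES.get(group, (2.0, 20.0))
    price = float(rng.uniform(plo, phi))
    subsidized = round(price * float(rng.uniform(0.4, 0.8)), 2) if rng.random() < 0.5 else None
    return FoodItem(
        id=f"{group.value}_{idx}",
        name=f"synthetic {group.value.replace('_', ' ')} {idx}",
        group=group,
        nutrients_per_100g=NutrientVector(vals),
        retail_price_per_kg=round(price, 2),
        subsidized_price_per_kg=subsidized,
    )


def _draw_infeasible_food(rng: np.random.Generator, group: FoodGroup, idx: int) -> FoodItem:
    """Food whose fat:energy density ratio is capped so the fat band cannot be
    met under the energy ceiling (the infeasibility certificate)."""
    food = _draw_food(rng, group, idx)
    vals = food.nutrients_per_100g.as_dict()
    energy = max(vals["energy_kcal"], 50.0)
    max_ratio = float(rng.uniform(0.005, 0.03))  # g fat per kcal
    vals["fat_g"] = min(vals["fat_g"], max_ratio * energy)
    vals["energy_kcal"] = energy
    return FoodItem(
        id=food.id,
        name=food.name,
        group=group,
        nutrients_per_100g=NutrientVector(vals),
        retail_price_per_kg=food.retail_price_per_kg,
        subsidized_price_per_kg=food.subsidized_price_per_kg,
    )


def _pick(db: FoodDatabase, group: FoodGroup, which: int = 0) -> str:
    return db.foods_in_group(group)[which].id


def _add_recipes(rng: np.random.Generator, db: FoodDatabase) -> None:
    cereal = _pick(db, FoodGroup.CEREALS_AND_MILLETS)
    cereal2 = db.foods_in_group(FoodGroup.CEREALS_AND_MILLETS)[-1].id
    pulse = _pick(db, FoodGroup.PULSES_AND_LEGUMES)
    oil = _pick(db, FoodGroup.EDIBLE_OILS_AND_FATS)
    glv = _pick(db, FoodGroup.GREEN_LEAFY_VEGETABLES)
    tuber = _pick(db, FoodGroup.ROOTS_AND_TUBERS)
    egg = _pick(db, FoodGroup.EGG)
    milk = _pick(db, FoodGroup.MILK_AND_MILK_PRODUCTS)
    sugar = _pick(db, FoodGroup.SUGARS)

    def r(id, category, ingredients, serving, compulsory=False):
        db.recipes[id] = Recipe(
            id=id,
            name=id.replace("_", " "),
            category=category,
            ingredients=tuple(ingredients),
            serving_size_g=serving,
            compulsory_eligible=compulsory,
        )

    u = lambda lo, hi: float(rng.uniform(lo, hi))
    r("main_cereal_1", RecipeCategory.MAIN_DISH,
      [(cereal, u(45, 60)), (oil, u(4, 8))], 180.0)
    r("main_cereal_2", RecipeCategory.MAIN_DISH,
      [(cereal2, u(40, 55)), (oil, u(3, 6))], 150.0)
    r("curry_pulse", RecipeCategory.CURRY,
      [(pulse, u(20, 30)), (oil, u(6, 10)), (glv, u(8, 12))], 150.0)
    r("curry_tuber", RecipeCategory.CURRY,
      [(tuber, u(60, 90)), (oil, u(4, 7))], 140.0)
    r("side_salad", RecipeCategory.SIDE_DISH, [(glv, u(15, 25))], 40.0)
    r("boiled_egg", RecipeCategory.ADDITIONAL, [(egg, 50.0)], 50.0, compulsory=True)
    r("milk_snack", RecipeCategory.SNACK,
      [(milk, u(15, 25)), (sugar, u(8, 12))], 120.0, compulsory=True)


def generate_food_db(spec: FixtureSpec) -> FoodDatabase:
    """Generate a reproducible synthetic database per the fixture spec.

    In ``guaranteed_feasible`` mode the database is certified by actually
    solving the default take-home-ration model (child 1-3 y) and, when recipes
    are included, the default meal model (child 3-6 y with the egg recipe
    compulsory); generation retries with fresh draws until both solve.  In
    ``guaranteed_infeasible`` mode every food's fat:energy density is capped
    at 0.03 g/kcal, so fat intake cannot exceed 0.03 x (energy ceiling)
    < 0.9 x fat target: the fat band is unattainable by construction.
    """
    rng = np.random.default_rng(spec.seed)
    last_err = None
    for _attempt in range(spec.max_retries):
        db = FoodDatabase()
        draw = _draw_infeasible_food if spec.mode == GUARANTEED_INFEASIBLE else _draw_food
        for group, n in spec.n_foods_per_group.items():
            for idx in range(n):
                food = draw(rng, group, idx)
                db.foods[food.id] = food
        if spec.include_recipes and all(
            db.foods_in_group(g)
            for g in (
                FoodGroup.CEREALS_AND_MILLETS, FoodGroup.PULSES_AND_LEGUMES,
                FoodGroup.EDIBLE_OILS_AND_FATS, FoodGroup.GREEN_LEAFY_VEGETABLES,
                FoodGroup.ROOTS_AND_TUBERS, FoodGroup.EGG,
                FoodGroup.MILK_AND_MILK_PRODUCTS, FoodGroup.SUGARS,
            )
        ):
            _add_recipes(rng, db)
        db.validate()
        if spec.mode != GUARANTEED_FEASIBLE:
            if spec.mode == GUARANTEED_INFEASIBLE:
                _check_infeasibility_certificate(db)
            return db
        ok, last_err = _verify_feasible(db)
        if ok:
            return db
    raise FixtureError(
        f"could not construct a guaranteed_feasible database in "
        f"{spec.max_retries} attempts (last failure: {last_err})"
    )


def _check_infeasibility_certificate(db: FoodDatabase) -> None:
    from .guidelines import DEFAULT_MACRO_BAND

    gl = default_guidelines(BeneficiaryCategory.CHILD_1_3Y)
    e_hi = gl.targets["energy_kcal"] * DEFAULT_MACRO_BAND["energy_kcal"][1]
    f_lo = gl.targets["fat_g"] * DEFAULT_MACRO_BAND["fat_g"][0]
    worst = 0.0
    for food in db.foods.values():
        n = food.nutrients_per_100g
        if n["energy_kcal"] > 0:
            worst = max(worst, n["fat_g"] / n["energy_kcal"])
    if worst * e_hi >= f_lo:
        raise FixtureError(
            f"infeasibility certificate failed: max fat/energy ratio {worst:.4f} "
            f"x energy ceiling {e_hi} reaches the fat floor {f_lo}"
        )


def _verify_feasible(db: FoodDatabase) -> tuple[bool, str | None]:
    from .hcm import MealConfig, optimize_meal
    from .thr import THRConfig, optimize_thr

    thr_sols = optimize_thr(db, default_guidelines(BeneficiaryCategory.CHILD_1_3Y), THRConfig())
    if not thr_sols[0].feasible:
        return False, f"THR infeasible (hint: {thr_sols[0].infeasibility_hint})"
    if db.recipes:
        selection = [
            rid for rid, rec in db.recipes.items()
            if rec.category is not RecipeCategory.SNACK and rid != "boiled_egg"
        ]
        meal_sols = optimize_meal(
            db,
            default_guidelines(BeneficiaryCategory.CHILD_3_6Y),
            selection,
            MealConfig(compulsory_recipe_ids=("boiled_egg",)),
        )
        if not meal_sols[0].feasible:
            return False, f"HCM infeasible (hint: {meal_sols[0].infeasibility_hint})"
    return True, None


# ---------------------------------------------------------------------------
# Hand-built toy instances

def random_small_instance(seed: int):
    """A random 4-5 food least-cost instance small enough for a 1 g grid.

    Quantity windows are sized so the full grid stays within the brute-force
    oracle's combination budget; constraint structure (group inclusion,
    cereal:pulse ratio) varies with the seed.  Instances are not guaranteed
    feasible — solver/oracle status agreement is part of what they exercise.
    """
    from .lp_engine import CONTINUOUS_GRAMS, ConstraintSet, DecisionSpec, RatioConstraint

    rng = np.random.default_rng(seed)
    plan = [
        (FoodGroup.CEREALS_AND_MILLETS, (5.0, 50.0)),
        (FoodGroup.PULSES_AND_LEGUMES, (5.0, 25.0)),
        (FoodGroup.EDIBLE_OILS_AND_FATS, (5.0, 15.0)),
        (FoodGroup.SUGARS, (5.0, 15.0)),
    ]
    if rng.random() < 0.6:
        plan.append((FoodGroup.MILK_AND_MILK_PRODUCTS, (5.0, 30.0)))
    decisions = []
    for group, bounds in plan:
        food = _draw_food(rng, group, 0)
        decisions.append(
            DecisionSpec(
                item_id=food.id,
                kind=CONTINUOUS_GRAMS,
                bounds=bounds,
                unit_cost=food.retail_price_per_kg / 1000.0,
                unit_nutrients=food.nutrients_per_100g * 0.01,
                unit_weight=1.0,
                group=group.value,
            )
        )
    e_lo = float(rng.uniform(250, 380))
    constraints = ConstraintSet(
        nutrient_lower={
            "energy_kcal": e_lo,
            "protein_g": float(rng.uniform(8, 13)),
            "fat_g": float(rng.uniform(6, 12)),
        },
        nutrient_upper={"energy_kcal": e_lo * 1.25},
    )
    if rng.random() < 0.5:
        constraints.group_min_count = {g.value: 1 for g, _ in plan[:4]}
    if rng.random() < 0.5:
        constraints.ratio_constraints = [
            RatioConstraint(
                name="cereal_to_pulse",
                numerator_groups=(FoodGroup.CEREALS_AND_MILLETS.value,),
                denominator_groups=(FoodGroup.PULSES_AND_LEGUMES.value,),
                ratio=2.0,
                tolerance=0.05,
            )
        ]
    return decisions, constraints


def four_food_instance():
    """A 4-food cereal/pulse/oil/sugar model used to exercise the generic
    engine directly: energy >= 400 kcal, protein >= 15 g, fat >= 15 g,
    cereal mass = 2 x pulse mass (2% tolerance)."""
    from .lp_engine import CONTINUOUS_GRAMS, ConstraintSet, DecisionSpec, RatioConstraint

    rows = [
        ("cereal", "cereals_and_millets", 350.0, 10.0, 1.0, 3.0, 120.0),
        ("pulse", "pulses_and_legumes", 340.0, 22.0, 1.5, 8.0, 60.0),
        ("oil", "edible_oils_and_fats", 900.0, 0.0, 100.0, 12.0, 25.0),
        ("sugar", "sugars", 400.0, 0.0, 0.0, 4.0, 30.0),
    ]
    decisions = [
        DecisionSpec(
            item_id=name,
            kind=CONTINUOUS_GRAMS,
            bounds=(0.0, qmax),
            unit_cost=price_kg / 1000.0,
            unit_nutrients=NutrientVector(
                {"energy_kcal": e / 100, "protein_g": p / 100, "fat_g": f / 100}
            ),
            unit_weight=1.0,
            group=group,
        )
        for name, group, e, p, f, price_kg, qmax in rows
    ]
    constraints = ConstraintSet(
        nutrient_lower={"energy_kcal": 400.0, "protein_g": 15.0, "fat_g": 15.0},
        ratio_constraints=[
            RatioConstraint(
                name="cereal_to_pulse",
                numerator_groups=("cereals_and_millets",),
                denominator_groups=("pulses_and_legumes",),
                ratio=2.0,
                tolerance=0.02,
            )
        ],
    )
    return decisions, constraints

def _thr_toy_5_db() -> FoodDatabase:
    db = FoodDatabase()

    def food(id, group, energy, protein, fat, price, subsidized=None, **extra):
        db.foods[id] = FoodItem(
            id=id,
            name=id.replace("_", " "),
            group=group,
            nutrients_per_100g=NutrientVector(
                {"energy_kcal": energy, "protein_g": protein, "fat_g": fat, **extra}
            ),
            retail_price_per_kg=price,
            subsidized_price_per_kg=subsidized,
        )

    food("rice", FoodGroup.CEREALS_AND_MILLETS, 350, 10, 1, 3.0, iron_mg=1.2)
    food("green_gram", FoodGroup.PULSES_AND_LEGUMES, 340, 22, 1.5, 8.0,
         iron_mg=4.4, folate_ug=140)
    food("sunflower_oil", FoodGroup.EDIBLE_OILS_AND_FATS, 900, 0, 100, 12.0)
    food("sugar", FoodGroup.SUGARS, 400, 0, 0, 4.0)
    # synthetic subsidized price; dense milk-powder item makes the macro bands
    # attainable alongside the 2:1 cereal:pulse blend
    food("milk_powder", FoodGroup.MILK_AND_MILK_PRODUCTS, 496, 25.8, 26.7, 25.9,
         subsidized=20.0, calcium_mg=950)
    db.validate()
    return db


def _hcm_toy_db() -> FoodDatabase:
    db = FoodDatabase()

    def food(id, group, energy, protein, fat, price, subsidized=None):
        db.foods[id] = FoodItem(
            id=id,
            name=id.replace("_", " "),
            group=group,
            nutrients_per_100g=NutrientVector(
                {"energy_kcal": energy, "protein_g": protein, "fat_g": fat}
            ),
            retail_price_per_kg=price,
            subsidized_price_per_kg=subsidized,
        )

    food("rice", FoodGroup.CEREALS_AND_MILLETS, 350, 7, 0.5, 3.0)
    food("wheat", FoodGroup.CEREALS_AND_MILLETS, 346, 11, 1.5, 3.5)
    food("green_gram", FoodGroup.PULSES_AND_LEGUMES, 334, 24, 1.2, 8.0)
    food("sunflower_oil", FoodGroup.EDIBLE_OILS_AND_FATS, 900, 0, 100, 12.0)
    food("potato", FoodGroup.ROOTS_AND_TUBERS, 97, 1.6, 0.1, 2.0)
    food("spinach", FoodGroup.GREEN_LEAFY_VEGETABLES, 24, 2, 0.4, 4.0)
    food("egg", FoodGroup.EGG, 155, 13, 11, 100.0, subsidized=50.0)
    food("peanut", FoodGroup.NUTS_AND_DRY_FRUITS, 567, 26, 49, 10.0)
    food("sugar", FoodGroup.SUGARS, 400, 0, 0, 4.0)

    def recipe(id, category, ingredients, serving, compulsory=False):
        db.recipes[id] = Recipe(
            id=id,
            name=id.replace("_", " "),
            category=category,
            ingredients=tuple(ingredients),
            serving_size_g=serving,
            compulsory_eligible=compulsory,
        )

    recipe("rice_main", RecipeCategory.MAIN_DISH, [("rice", 50.0), ("sunflower_oil", 6.0)], 180.0)
    recipe("roti_main", RecipeCategory.MAIN_DISH, [("wheat", 45.0), ("sunflower_oil", 3.0)], 120.0)
    recipe(
        "dal_curry",
        RecipeCategory.CURRY,
        [("green_gram", 25.0), ("sunflower_oil", 8.0), ("spinach", 10.0)],
        150.0,
    )
    recipe("potato_curry", RecipeCategory.CURRY, [("potato", 80.0), ("sunflower_oil", 5.0)], 140.0)
    recipe("salad_side", RecipeCategory.SIDE_DISH, [("spinach", 20.0)], 40.0)
    recipe("boiled_egg", RecipeCategory.ADDITIONAL, [("egg", 50.0)], 50.0, compulsory=True)
    recipe(
        "peanut_ladoo",
        RecipeCategory.SNACK,
        [("peanut", 20.0), ("sugar", 10.0)],
        30.0,
        compulsory=True,
    )
    db.validate()
    return db


def toy_instances() -> dict[str, dict]:
    """Hand-built instances used across examples and verification.

    ``thr_toy_5``: 5 raw foods (cereal, pulse, oil, sugar, milk powder) with
    quantity windows sized so a 1 g grid search stays tractable.
    ``hcm_toy``: 2 mains, 2 curries, 1 side, a compulsory egg recipe, and a
    snack for SAM augmentation.
    """
    from .hcm import MealConfig
    from .thr import THRConfig

    thr_config = THRConfig(
        item_windows={
            "rice": (5.0, 60.0),
            "green_gram": (5.0, 30.0),
            "sunflower_oil": (5.0, 15.0),
            "sugar": (5.0, 15.0),
            "milk_powder": (5.0, 40.0),
        }
    )
    hcm_selection = ["rice_main", "roti_main", "dal_curry", "potato_curry", "salad_side"]
    return {
        "thr_toy_5": {
            "db": _thr_toy_5_db(),
            "guidelines": default_guidelines(BeneficiaryCategory.CHILD_1_3Y),
            "config": thr_config,
        },
        "hcm_toy": {
            "db": _hcm_toy_db(),
            "guidelines": default_guidelines(BeneficiaryCategory.CHILD_3_6Y),
            "selection": hcm_selection,
            "config": MealConfig(compulsory_recipe_ids=("boiled_egg",)),
        },
    }
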