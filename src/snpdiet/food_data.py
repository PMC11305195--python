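"""Food and recipe data model with CSV/JSON I/O.

Foods carry per-100 g nutrient vectors (edible-portion basis, following food
composition table convention) and prices per kg; prices are converted to
per-gram internally.  Recipes are ingredient lists in raw grams per serving;
their per-serving nutrients, cost and weight are always derived on demand,
never stored.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .nutrients import NUTRIENT_FIELDS, NutrientVector

logger = logging.getLogger(__name__)


class FoodDataError(ValueError):
    """Raised for schema, validation, or referential-integrity failures."""


class FoodGroup(enum.Enum):
    CEREALS_AND_MILLETS = "cereals_and_millets"
    PULSES_AND_LEGUMES = "pulses_and_legumes"
    GREEN_LEAFY_VEGETABLES = "green_leafy_vegetables"
    OTHER_VEGETABLES = "other_vegetables"
    ROOTS_AND_TUBERS = "roots_and_tubers"
    FRUITS = "fruits"
    EGG = "egg"
    MILK_AND_MILK_PRODUCTS = "milk_and_milk_products"
    NUTS_AND_DRY_FRUITS = "nuts_and_dry_fruits"
    SUGARS = "sugars"
    EDIBLE_OILS_AND_FATS = "edible_oils_and_fats"

    @classmethod
    def parse(cls, label: str) -> "FoodGroup":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(g.value for g in cls)
            raise FoodDataError(
                f"unknown food group {label!r}; valid groups: {valid}"
            ) from None


class RecipeCategory(enum.Enum):
    MAIN_DISH = "main_dish"
    CURRY = "curry"
    SIDE_DISH = "side_dish"
    SNACK = "snack"
    ADDITIONAL = "additional"


@dataclass(frozen=True)
class FoodItem:
    """A raw food: group, per-100 g nutrients, prices per kg, fortification."""

    id: str
    name: str
    group: FoodGroup
    nutrients_per_100g: NutrientVector
    retail_price_per_kg: float
    subsidized_price_per_kg: float | None = None
    fortified: bool = False
    fortification_overlay: NutrientVector | None = None
    premix_eligible: bool = False
    local_names: tuple[str, ...] = ()
    state_tags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.id:
            raise FoodDataError("food id must be nonempty")
        if not self.retail_price_per_kg > 0:
            raise FoodDataError(
                f"food {self.id!r}: retail_price_per_kg must be > 0, "
                f"got {self.retail_price_per_kg}"
            )
        if self.subsidized_price_per_kg is not None and not self.subsidized_price_per_kg > 0:
            raise FoodDataError(
                f"food {self.id!r}: subsidized_price_per_kg must be > 0, "
                f"got {self.subsidized_price_per_kg}"
            )
        if self.fortification_overlay is not None and not self.fortified:
            raise FoodDataError(
                f"food {self.id!r}: fortification_overlay present but fortified is false"
            )


@dataclass(frozen=True)
class Recipe:
    """A categorized dish: ingredient grams per serving and a serving size.

    ``serving_size_g`` is the predetermined lower-limit serving (the quantity a
    beneficiary can reasonably consume at one sitting); optimization scales it
    by a bounded multiplier.  ``compulsory_eligible`` is true only for egg /
    milk / milk-powder based items.
    """

    id: str
    name: str
    category: RecipeCategory
    ingredients: tuple[tuple[str, float], ...]
    serving_size_g: float
    compulsory_eligible: bool = False

    def __post_init__(self):
        if not self.id:
            raise FoodDataError("recipe id must be nonempty")
        if not self.serving_size_g > 0:
            raise FoodDataError(f"recipe {self.id!r}: serving_size_g must be > 0")
        for food_id, grams in self.ingredients:
            if not grams > 0:
                raise FoodDataError(
                    f"recipe {self.id!r}: ingredient {food_id!r} grams must be > 0"
                )


@dataclass
class FoodDatabase:
    """Keyed collections of foods and recipes with referential integrity."""

    foods: dict[str, FoodItem] = field(default_factory=dict)
    recipes: dict[str, Recipe] = field(default_factory=dict)
    currency_label: str = "INR"

    def validate(self) -> None:
        for rid, recipe in self.recipes.items():
            for food_id, _ in recipe.ingredients:
                if food_id not in self.foods:
                    raise FoodDataError(
                        f"recipe {rid!r} references unknown food id {food_id!r}"
                    )

    def foods_in_group(self, group: FoodGroup) -> list[FoodItem]:
        return [f for f in self.foods.values() if f.group is group]

    def recipes_in_category(self, category: RecipeCategory) -> list[Recipe]:
        return [r for r in self.recipes.values() if r.category is category]


# ---------------------------------------------------------------------------
# Derivations

def effective_price_per_gram(food: FoodItem, use_subsidy: bool) -> float:
    """Price per gram: subsidized when requested and available, else retail."""
    if use_subsidy and food.subsidized_price_per_kg is not None:
        return food.subsidized_price_per_kg / 1000.0
    return food.retail_price_per_kg / 1000.0


def effective_nutrients_per_100g(
    food: FoodItem, apply_fortification: bool
) -> NutrientVector:
    """Per-100 g nutrients, with the additive fortification overlay when enabled."""
    if apply_fortification and food.fortified and food.fortification_overlay is not None:
        return food.nutrients_per_100g + food.fortification_overlay
    return food.nutrients_per_100g


def recipe_profile(
    recipe: Recipe,
    db: FoodDatabase,
    use_subsidy: bool = False,
    apply_fortification: bool = True,
) -> tuple[NutrientVector, float, float]:
    """Per-serving (nutrients, cost, raw weight in g) of a recipe.

    Linear in the ingredient grams: nutrients are the grams/100-weighted sum of
    each ingredient's effective per-100 g vector, cost is grams times the
    effective per-gram price.
    """
    nutrients = NutrientVector()
    cost = 0.0
    weight = 0.0
    for food_id, grams in recipe.ingredients:
        food = db.foods.get(food_id)
        if food is None:
            raise FoodDataError(
                f"recipe {recipe.id!r} references unknown food id {food_id!r}"
            )
        nutrients = nutrients + (grams / 100.0) * effective_nutrients_per_100g(
            food, apply_fortification
        )
        cost += grams * effective_price_per_gram(food, use_subsidy)
        weight += grams
    return nutrients, cost, weight


# ---------------------------------------------------------------------------
# File I/O

FOOD_CSV_COLUMNS = (
    ("id", "name", "group")
    + NUTRIENT_FIELDS[:4]
    + NUTRIENT_FIELDS[4:]
    + ("retail_price_per_kg", "subsidized_price_per_kg", "fortified", "premix_eligible")
)
# flatten to the documented exact header
FOOD_CSV_COLUMNS = (
    "id",
    "name",
    "group",
    *NUTRIENT_FIELDS,
    "retail_price_per_kg",
    "subsidized_price_per_kg",
    "fortified",
    "premix_eligible",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(raw: str, where: str) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise FoodDataError(f"{where}: cannot parse boolean from {raw!r}")


def _parse_food_row(row: dict[str, str], rownum: int) -> FoodItem:
    where = f"row {rownum}"
    nutrient_vals = {}
    for name in NUTRIENT_FIELDS:
        raw = (row.get(name) or "").strip()
        if raw == "":
            logger.warning("%s (%s): missing %s treated as 0", where, row.get("id"), name)
            nutrient_vals[name] = 0.0
            continue
        try:
            v = float(raw)
        except ValueError:
            raise FoodDataError(f"{where}, field {name!r}: not a number: {raw!r}") from None
        if v < 0:
            raise FoodDataError(f"{where}, field {name!r}: negative value {v}")
        nutrient_vals[name] = v
    try:
        retail = float(row["retail_price_per_kg"])
    except ValueError:
        raise FoodDataError(
            f"{where}, field 'retail_price_per_kg': not a number: "
            f"{row['retail_price_per_kg']!r}"
        ) from None
    if retail <= 0:
        raise FoodDataError(
            f"{where}, field 'retail_price_per_kg': must be > 0, got {retail}"
        )
    sub_raw = (row.get("subsidized_price_per_kg") or "").strip()
    subsidized = None
    if sub_raw:
        subsidized = float(sub_raw)
        if subsidized <= 0:
            raise FoodDataError(
                f"{where}, field 'subsidized_price_per_kg': must be > 0, got {subsidized}"
            )
    return FoodItem(
        id=row["id"].strip(),
        name=row["name"].strip(),
        group=FoodGroup.parse(row["group"].strip()),
        nutrients_per_100g=NutrientVector(nutrient_vals),
        retail_price_per_kg=retail,
        subsidized_price_per_kg=subsidized,
        fortified=_parse_bool(row.get("fortified", ""), where),
        premix_eligible=_parse_bool(row.get("premix_eligible", ""), where),
    )


def _food_from_record(rec: dict, where: str) -> FoodItem:
    overlay = rec.get("fortification_overlay")
    return FoodItem(
        id=rec["id"],
        name=rec.get("name", rec["id"]),
        group=FoodGroup.parse(rec["group"]),
        nutrients_per_100g=NutrientVector(rec["nutrients_per_100g"]),
        retail_price_per_kg=float(rec["retail_price_per_kg"]),
        subsidized_price_per_kg=(
            float(rec["subsidized_price_per_kg"])
            if rec.get("subsidized_price_per_kg") is not None
            else None
        ),
        fortified=bool(rec.get("fortified", False)),
        fortification_overlay=NutrientVector(overlay) if overlay is not None else None,
        premix_eligible=bool(rec.get("premix_eligible", False)),
        local_names=tuple(rec.get("local_names", ()) or ()),
        state_tags=tuple(rec.get("state_tags", ()) or ()),
    )


def load_food_database(path: str | Path, format: str | None = None) -> FoodDatabase:
    """Load a food database from CSV (foods only) or JSON (foods + recipes).

    Validation failures raise :class:`FoodDataError` naming the offending row
    or record and field.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return _load_csv(path)
    if format == "json":
        return _load_json(path)
    raise FoodDataError(f"unknown format {format!r} (expected 'csv' or 'json')")


def _load_csv(path: Path) -> FoodDatabase:
    db = FoodDatabase()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in FOOD_CSV_COLUMNS if c not in header]
        if missing:
            raise FoodDataError(f"{path}: missing required column(s): {missing}")
        for rownum, row in enumerate(reader, start=2):  # header is row 1
            food = _parse_food_row(row, rownum)
            if food.id in db.foods:
                raise FoodDataError(f"row {rownum}: duplicate food id {food.id!r}")
            db.foods[food.id] = food
    db.validate()
    return db


def _load_json(path: Path) -> FoodDatabase:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    db = FoodDatabase(currency_label=doc.get("currency_label", "INR"))
    for i, rec in enumerate(doc.get("foods", [])):
        food = _food_from_record(rec, f"foods[{i}]")
        if food.id in db.foods:
            raise FoodDataError(f"foods[{i}]: duplicate food id {food.id!r}")
        db.foods[food.id] = food
    for i, rec in enumerate(doc.get("recipes", [])):
        try:
            category = RecipeCategory(rec["category"])
        except ValueError:
            raise FoodDataError(
                f"recipes[{i}]: unknown category {rec['category']!r}"
            ) from None
        recipe = Recipe(
            id=rec["id"],
            name=rec.get("name", rec["id"]),
            category=category,
            ingredients=tuple((ing["food_id"], float(ing["grams"])) for ing in rec["ingredients"]),
            serving_size_g=float(rec["serving_size_g"]),
            compulsory_eligible=bool(rec.get("compulsory_eligible", False)),
        )
        if recipe.id in db.recipes:
            raise FoodDataError(f"recipes[{i}]: duplicate recipe id {recipe.id!r}")
        db.recipes[recipe.id] = recipe
    db.validate()
    return db


def save_food_database(db: FoodDatabase, path: str | Path, format: str | None = None) -> None:
    """Write a database as CSV (foods only) or JSON (full)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(FOOD_CSV_COLUMNS)
            for food in db.foods.values():
                nd = food.nutrients_per_100g.as_dict()
                writer.writerow(
                    [food.id, food.name, food.group.value]
                    + [repr(nd[n]) for n in NUTRIENT_FIELDS]
                    + [
                        repr(food.retail_price_per_kg),
                        "" if food.subsidized_price_per_kg is None
                        else repr(food.subsidized_price_per_kg),
                        str(food.fortified).lower(),
                        str(food.premix_eligible).lower(),
                    ]
                )
    elif format == "json":
        doc = {
            "currency_label": db.currency_label,
            "foods": [
                {
                    "id": f.id,
                    "name": f.name,
                    "group": f.group.value,
                    "nutrients_per_100g": f.nutrients_per_100g.as_dict(),
                    "retail_price_per_kg": f.retail_price_per_kg,
                    "subsidized_price_per_kg": f.subsidized_price_per_kg,
                    "fortified": f.fortified,
                    "fortification_overlay": (
                        f.fortification_overlay.as_dict()
                        if f.fortification_overlay is not None
                        else None
                    ),
                    "premix_eligible": f.premix_eligible,
                    "local_names": list(f.local_names),
                    "state_tags": list(f.state_tags),
                }
                for f in db.foods.values()
            ],
            "recipes": [
                {
                    "id": r.id,
                    "name": r.name,
                    "category": r.category.value,
                    "ingredients": [
                        {"food_id": fid, "grams": g} for fid, g in r.ingredients
                    ],
                    "serving_size_g": r.serving_size_g,
                    "compulsory_eligible": r.compulsory_eligible,
                }
                for r in db.recipes.values()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise FoodDataError(f"unknown format {format!r}")
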