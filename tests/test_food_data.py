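import math

import pytest

from snpdiet.food_data import (
    FOOD_CSV_COLUMNS,
    FoodDatabase,
    FoodDataError,
    FoodGroup,
    FoodItem,
    Recipe,
    RecipeCategory,
    effective_nutrients_per_100g,
    effective_price_per_gram,
    load_food_database,
    recipe_profile,
    save_food_database,
)
from snpdiet.nutrients import NUTRIENT_FIELDS, NutrientVector


def _food(id="rice", price=5.0, subsidized=None, **kwargs):
    return FoodItem(
        id=id,
        name=id,
        group=kwargs.pop("group", FoodGroup.CEREALS_AND_MILLETS),
        nutrients_per_100g=kwargs.pop(
            "nutrients", NutrientVector({"energy_kcal": 350.0, "protein_g": 8.0})
        ),
        retail_price_per_kg=price,
        subsidized_price_per_kg=subsidized,
        **kwargs,
    )


class TestPrices:
    def test_retail_price_converts_per_kg_to_per_gram(self):
        assert effective_price_per_gram(_food(price=5.0), use_subsidy=False) == 0.005

    def test_subsidized_price_used_when_enabled(self):
        food = _food(price=5.0, subsidized=2.5)
        assert effective_price_per_gram(food, use_subsidy=True) == 0.0025

    def test_subsidy_flag_off_keeps_retail(self):
        food = _food(price=5.0, subsidized=2.5)
        assert effective_price_per_gram(food, use_subsidy=False) == 0.005

    def test_subsidy_never_increases_price(self):
        for sub in (None, 2.5, 4.9, 5.0):
            food = _food(price=5.0, subsidized=sub)
            assert effective_price_per_gram(food, True) <= effective_price_per_gram(food, False)


class TestFortification:
    def test_overlay_adds_componentwise(self):
        food = _food(
            id="oil",
            group=FoodGroup.EDIBLE_OILS_AND_FATS,
            nutrients=NutrientVector({"energy_kcal": 900.0, "fat_g": 100.0}),
            fortified=True,
            fortification_overlay=NutrientVector({"vitamin_a_ug": 750.0}),
        )
        out = effective_nutrients_per_100g(food, apply_fortification=True)
        assert out["vitamin_a_ug"] == 750.0
        assert out["energy_kcal"] == 900.0

    def test_toggle_off_returns_base(self):
        food = _food(
            fortified=True, fortification_overlay=NutrientVector({"iron_mg": 10.0})
        )
        assert effective_nutrients_per_100g(food, False) == food.nutrients_per_100g

    def test_overlay_without_fortified_flag_rejected(self):
        with pytest.raises(FoodDataError, match="fortification_overlay"):
            _food(fortified=False, fortification_overlay=NutrientVector({"iron_mg": 1.0}))


class TestRecipeProfile:
    def test_single_ingredient_linear_scaling(self):
        db = FoodDatabase(foods={"rice": _food()})
        recipe = Recipe(
            id="r", name="r", category=RecipeCategory.MAIN_DISH,
            ingredients=(("rice", 50.0),), serving_size_g=120.0,
        )
        nutrients, cost, weight = recipe_profile(recipe, db)
        assert nutrients["energy_kcal"] == pytest.approx(175.0)
        assert cost == pytest.approx(50 * 0.005)
        assert weight == 50.0

    def test_three_ingredient_totals_match_independent_summation(self):
        foods = {
            "a": _food("a", price=3.0, nutrients=NutrientVector({"energy_kcal": 350, "iron_mg": 2.0})),
            "b": _food("b", price=8.0, group=FoodGroup.PULSES_AND_LEGUMES,
                       nutrients=NutrientVector({"energy_kcal": 340, "protein_g": 22})),
            "c": _food("c", price=12.0, group=FoodGroup.EDIBLE_OILS_AND_FATS,
                       nutrients=NutrientVector({"energy_kcal": 900, "fat_g": 100})),
        }
        grams = {"a": 40.0, "b": 25.0, "c": 7.5}
        db = FoodDatabase(foods=foods)
        recipe = Recipe(
            id="r", name="r", category=RecipeCategory.CURRY,
            ingredients=tuple(grams.items()), serving_size_g=150.0,
        )
        nutrients, cost, weight = recipe_profile(recipe, db)
        # spreadsheet-style oracle: per-nutrient sum of grams/100 x per-100g
        for nut in NUTRIENT_FIELDS:
            expected = sum(
                grams[f] / 100.0 * foods[f].nutrients_per_100g[nut] for f in grams
            )
            assert nutrients[nut] == pytest.approx(expected, rel=1e-12)
        assert cost == pytest.approx(sum(grams[f] * foods[f].retail_price_per_kg / 1000 for f in grams))
        assert weight == pytest.approx(sum(grams.values()))

    def test_doubling_ingredients_doubles_everything(self):
        db = FoodDatabase(foods={"rice": _food()})
        r1 = Recipe(id="r1", name="", category=RecipeCategory.MAIN_DISH,
                    ingredients=(("rice", 30.0),), serving_size_g=100.0)
        r2 = Recipe(id="r2", name="", category=RecipeCategory.MAIN_DISH,
                    ingredients=(("rice", 60.0),), serving_size_g=100.0)
        n1, c1, w1 = recipe_profile(r1, db)
        n2, c2, w2 = recipe_profile(r2, db)
        assert c2 == pytest.approx(2 * c1) and w2 == pytest.approx(2 * w1)
        assert all(
            n2[nut] == pytest.approx(2 * n1[nut], abs=1e-12) for nut in NUTRIENT_FIELDS
        )

    def test_empty_recipe_is_all_zero(self):
        db = FoodDatabase()
        recipe = Recipe(id="r", name="", category=RecipeCategory.SIDE_DISH,
                        ingredients=(), serving_size_g=10.0)
        nutrients, cost, weight = recipe_profile(recipe, db)
        assert cost == 0.0 and weight == 0.0
        assert all(v == 0 for v in nutrients.as_dict().values())

    def test_subsidy_never_increases_recipe_cost(self, hcm_toy):
        db = hcm_toy["db"]
        for recipe in db.recipes.values():
            _, retail, _ = recipe_profile(recipe, db, use_subsidy=False)
            _, subsidized, _ = recipe_profile(recipe, db, use_subsidy=True)
            assert subsidized <= retail + 1e-12


class TestFileIO:
    def test_csv_round_trip_preserves_values(self, tmp_path, thr_toy):
        db = thr_toy["db"]
        path = tmp_path / "foods.csv"
        save_food_database(db, path, format="csv")
        loaded = load_food_database(path, format="csv")
        assert set(loaded.foods) == set(db.foods)
        for fid, food in db.foods.items():
            got = loaded.foods[fid]
            assert got.group is food.group
            assert got.retail_price_per_kg == pytest.approx(
                food.retail_price_per_kg, rel=1e-12
            )
            for nut in NUTRIENT_FIELDS:
                assert got.nutrients_per_100g[nut] == pytest.approx(
                    food.nutrients_per_100g[nut], rel=1e-12
                )

    def test_json_round_trip_preserves_recipes(self, tmp_path, hcm_toy):
        db = hcm_toy["db"]
        path = tmp_path / "db.json"
        save_food_database(db, path, format="json")
        loaded = load_food_database(path, format="json")
        assert set(loaded.recipes) == set(db.recipes)
        for rid in db.recipes:
            assert loaded.recipes[rid].ingredients == db.recipes[rid].ingredients
            assert loaded.recipes[rid].category is db.recipes[rid].category

    def test_well_formed_csv_loads_all_rows(self, tmp_path):
        path = tmp_path / "ok.csv"
        header = ",".join(FOOD_CSV_COLUMNS)
        zeros = ",".join(["0"] * len(NUTRIENT_FIELDS))
        rows = [
            f"f{i},food {i},cereals_and_millets,{zeros},4.0,,false,false"
            for i in range(4)
        ]
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        db = load_food_database(path)
        assert len(db.foods) == 4 and len(db.recipes) == 0

    def test_negative_price_error_names_row_and_field(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = ",".join(FOOD_CSV_COLUMNS)
        zeros = ",".join(["0"] * len(NUTRIENT_FIELDS))
        rows = [
            f"a,a,sugars,{zeros},4.0,,false,false",
            f"b,b,sugars,{zeros},-2.0,,false,false",
        ]
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(FoodDataError, match=r"row 3.*retail_price_per_kg"):
            load_food_database(path)

    def test_unknown_ingredient_reference_rejected(self, tmp_path):
        path = tmp_path / "dangling.json"
        path.write_text(
            """{"foods": [], "recipes": [{"id": "r", "category": "curry",
            "ingredients": [{"food_id": "xyz", "grams": 10}], "serving_size_g": 50}]}"""
        )
        with pytest.raises(FoodDataError, match="xyz"):
            load_food_database(path)

    def test_duplicate_food_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        header = ",".join(FOOD_CSV_COLUMNS)
        zeros = ",".join(["0"] * len(NUTRIENT_FIELDS))
        row = f"a,a,sugars,{zeros},4.0,,false,false"
        path.write_text(header + "\n" + row + "\n" + row + "\n")
        with pytest.raises(FoodDataError, match="duplicate"):
            load_food_database(path)
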