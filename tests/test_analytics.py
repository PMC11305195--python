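import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpdiet import analytics
from snpdiet.analytics import (
    GREEN,
    ORANGE,
    RED,
    adequacy_color,
    contribution_breakdown,
    food_group_allocation,
    nutrient_ratio_radar,
    percent_of_guideline,
)
from snpdiet.guidelines import default_guidelines
from snpdiet.nutrients import NUTRIENT_FIELDS, NutrientVector
from snpdiet.worked_examples import HCM_CHILD_3_6Y, THR_CHILD_1_3Y


class TestPercentOfGuideline:
    @pytest.mark.parametrize(
        "nutrient, content, expected",
        [
            ("iron_mg", 3.4, 170.0),
            ("protein_g", 13.7, 91.3),
            ("energy_kcal", 400.0, 100.0),
        ],
    )
    def test_published_thr_rows_reproduced(self, nutrient, content, expected):
        gl = default_guidelines("child_1_3y")
        rows = {
            r.nutrient: r
            for r in percent_of_guideline(NutrientVector({nutrient: content}), gl)
        }
        assert rows[nutrient].percent == expected

    def test_content_equal_to_target_gives_100(self):
        gl = default_guidelines("child_3_6y")
        rows = percent_of_guideline(gl.targets, gl)
        for r in rows:
            if r.guideline > 0:
                assert r.percent == 100.0

    def test_zero_target_rows_flagged_not_computed(self):
        gl = default_guidelines("pregnant_woman")  # macros only
        rows = {r.nutrient: r for r in percent_of_guideline(NutrientVector(), gl)}
        assert rows["iron_mg"].percent is None
        assert rows["energy_kcal"].percent == 0.0

    def test_rounding_is_half_away_from_zero_to_one_decimal(self):
        gl = default_guidelines("child_1_3y").with_target("iron_mg", 4.0)
        rows = {
            r.nutrient: r
            for r in percent_of_guideline(NutrientVector({"iron_mg": 1.861}), gl)
        }
        # 46.525 -> 46.5 would be banker's; half away from zero gives 46.5?  use
        # an unambiguous half case: 1.862/4 = 46.55 -> 46.6
        assert rows["iron_mg"].percent == 46.5
        rows2 = {
            r.nutrient: r
            for r in percent_of_guideline(NutrientVector({"iron_mg": 1.862}), gl)
        }
        assert rows2["iron_mg"].percent == 46.6


class TestAdequacyColor:
    @pytest.mark.parametrize(
        "percent, mode, expected",
        [
            (53.0, "hcm", ORANGE),
            (60.0, "hcm", ORANGE),
            (60.0001, "hcm", GREEN),
            (30.0, "hcm", ORANGE),
            (29.9, "hcm", RED),
            (85.0, "thr", GREEN),
            (80.0, "thr", ORANGE),
            (50.0, "thr", ORANGE),
            (49.9, "thr", RED),
        ],
    )
    def test_threshold_boundaries(self, percent, mode, expected):
        assert adequacy_color(percent, mode) == expected

    @settings(deadline=None, max_examples=200)
    @given(
        a=st.floats(min_value=0, max_value=500),
        b=st.floats(min_value=0, max_value=500),
        mode=st.sampled_from(["hcm", "thr"]),
    )
    def test_color_is_monotone_in_percent(self, a, b, mode):
        order = {RED: 0, ORANGE: 1, GREEN: 2}
        lo, hi = min(a, b), max(a, b)
        assert order[adequacy_color(lo, mode)] <= order[adequacy_color(hi, mode)]

    def test_published_hcm_column_is_green_except_vitamin_b2(self):
        colors = {
            nut: adequacy_color(printed_pct, "hcm")
            for nut, (_, _, printed_pct) in HCM_CHILD_3_6Y.items()
        }
        assert colors.pop("vitamin_b2_mg") == ORANGE
        assert all(c == GREEN for c in colors.values())

    def test_published_table_rows_self_consistent(self):
        from snpdiet.analytics import round1
        from snpdiet.worked_examples import SELF_CONSISTENT

        for table, key in ((THR_CHILD_1_3Y, "thr_child_1_3y"), (HCM_CHILD_3_6Y, "hcm_child_3_6y")):
            for nut in SELF_CONSISTENT[key]:
                guideline, content, printed = table[nut]
                assert round1(100.0 * content / guideline) == printed


class TestAllocation:
    def _solution(self, quantities):
        from snpdiet.lp_engine import RationSolution

        return RationSolution(
            quantities=quantities,
            selected={k: v > 0 for k, v in quantities.items()},
            total_cost=1.0,
            nutrient_totals=NutrientVector(),
            status="optimal",
        )

    def test_single_food_gets_100_percent(self, thr_toy):
        shares = food_group_allocation(self._solution({"rice": 80.0}), thr_toy["db"])
        assert shares == {"cereals_and_millets": 100.0}

    def test_two_food_shares(self, thr_toy):
        shares = food_group_allocation(
            self._solution({"rice": 60.0, "green_gram": 30.0}), thr_toy["db"]
        )
        assert shares["cereals_and_millets"] == pytest.approx(200 / 3)
        assert shares["pulses_and_legumes"] == pytest.approx(100 / 3)

    def test_shares_sum_to_100_for_recipe_solution(self, hcm_toy):
        from snpdiet.hcm import optimize_meal

        sol = optimize_meal(
            hcm_toy["db"], hcm_toy["guidelines"], hcm_toy["selection"], hcm_toy["config"]
        )[0]
        shares = food_group_allocation(sol, hcm_toy["db"])
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_weight_solution_rejected(self, thr_toy):
        with pytest.raises(analytics.AnalyticsError):
            food_group_allocation(self._solution({}), thr_toy["db"])


class TestRadar:
    def test_published_iron_ratio(self):
        gl = default_guidelines("child_1_3y")
        ratios = nutrient_ratio_radar(NutrientVector({"iron_mg": 3.4}), gl)
        assert ratios["iron_mg"] == pytest.approx(1.70)

    def test_targets_met_exactly_give_unit_radar(self):
        gl = default_guidelines("child_3_6y")
        ratios = nutrient_ratio_radar(gl.targets, gl)
        for nut in NUTRIENT_FIELDS:
            if gl.targets[nut] > 0:
                assert ratios[nut] == pytest.approx(1.0)
            else:
                assert ratios[nut] is None

    def test_empty_diet_gives_zero_ratios(self):
        gl = default_guidelines("child_1_3y")
        ratios = nutrient_ratio_radar(NutrientVector(), gl)
        assert ratios["iron_mg"] == 0.0


class TestContributions:
    def test_contributions_sum_to_solution_totals(self, hcm_toy):
        from snpdiet.hcm import optimize_meal

        sol = optimize_meal(
            hcm_toy["db"], hcm_toy["guidelines"], hcm_toy["selection"], hcm_toy["config"]
        )[0]
        breakdown = contribution_breakdown(sol, hcm_toy["db"])
        for nut in NUTRIENT_FIELDS:
            total = sum(
                bucket[nut] for bucket in breakdown["nutrient_contributions"].values()
            )
            assert total == pytest.approx(sol.nutrient_totals[nut], rel=1e-6, abs=1e-9)
        assert sum(breakdown["cost_shares"].values()) == pytest.approx(100.0)

    def test_two_food_contributions_match_per_item_products(self, thr_toy):
        from snpdiet.lp_engine import RationSolution

        db = thr_toy["db"]
        q = {"rice": 40.0, "sunflower_oil": 10.0}
        sol = RationSolution(
            quantities=q,
            selected={k: True for k in q},
            total_cost=40 * 0.003 + 10 * 0.012,
            nutrient_totals=NutrientVector(),
            status="optimal",
        )
        breakdown = contribution_breakdown(sol, db)
        cereals = breakdown["nutrient_contributions"]["cereals_and_millets"]
        assert cereals["energy_kcal"] == pytest.approx(40 / 100 * 350)
        oils = breakdown["nutrient_contributions"]["edible_oils_and_fats"]
        assert oils["fat_g"] == pytest.approx(10 / 100 * 100)
        assert not breakdown["zero_cost"]
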