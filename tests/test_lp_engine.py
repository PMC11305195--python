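import copy
import math

import pytest

from snpdiet.fixtures import four_food_instance
from snpdiet.lp_engine import (
    CONTINUOUS_GRAMS,
    INFEASIBLE,
    OPTIMAL,
    ConstraintSet,
    DecisionSpec,
    ModelError,
    brute_force_oracle,
    check_solution,
    enumerate_k_best,
    solve_min_cost,
)
from snpdiet.nutrients import NutrientVector


def _single_food():
    return [
        DecisionSpec(
            item_id="f",
            kind=CONTINUOUS_GRAMS,
            bounds=(0.0, 200.0),
            unit_cost=0.01,
            unit_nutrients=NutrientVector({"energy_kcal": 4.0}),
            unit_weight=1.0,
            group="cereals_and_millets",
        )
    ]


class TestSolveMinCost:
    def test_single_food_closed_form(self):
        cons = ConstraintSet(
            nutrient_lower={"energy_kcal": 400.0}, nutrient_upper={"energy_kcal": 400.0}
        )
        sol = solve_min_cost(_single_food(), cons)
        assert sol.status == OPTIMAL
        assert sol.quantities["f"] == pytest.approx(100.0, rel=1e-6)
        assert sol.total_cost == pytest.approx(1.0, rel=1e-6)

    def test_four_food_toy_within_oracle_sandwich(self):
        decisions, constraints = four_food_instance()
        milp = solve_min_cost(decisions, constraints)
        oracle = brute_force_oracle(decisions, constraints, grid_step=1.0)
        assert milp.status == OPTIMAL and oracle.status == OPTIMAL
        # relaxation dominance + one grid step of slack per decision
        slack = max(d.unit_cost for d in decisions) * 1.0 * len(decisions)
        assert milp.total_cost <= oracle.total_cost + 1e-9
        assert milp.total_cost >= oracle.total_cost - slack
        assert check_solution(decisions, constraints, milp) == []

    def test_vacuous_energy_requirement_infeasible_with_hint(self):
        decisions = [
            DecisionSpec(
                item_id="water",
                kind=CONTINUOUS_GRAMS,
                bounds=(0.0, 500.0),
                unit_cost=0.001,
                unit_nutrients=NutrientVector(),
                unit_weight=1.0,
                group="other_vegetables",
            )
        ]
        cons = ConstraintSet(nutrient_lower={"energy_kcal": 400.0})
        sol = solve_min_cost(decisions, cons)
        assert sol.status == INFEASIBLE
        assert "nutrient_lower" in sol.infeasibility_hint

    def test_nutrient_totals_and_cost_recomputed_consistently(self):
        decisions, constraints = four_food_instance()
        sol = solve_min_cost(decisions, constraints)
        recomputed = sum(
            sol.quantities[d.item_id] * d.unit_cost for d in decisions
        )
        assert sol.total_cost == pytest.approx(recomputed, rel=1e-9)
        for d in decisions:
            if not sol.selected[d.item_id]:
                assert sol.quantities[d.item_id] == 0.0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            solve_min_cost(_single_food() * 2, ConstraintSet())


class TestProperties:
    def test_price_scaling_scales_cost(self):
        from dataclasses import replace

        decisions, constraints = four_food_instance()
        base = solve_min_cost(decisions, constraints)
        lam = 3.5
        scaled = [replace(d, unit_cost=lam * d.unit_cost) for d in decisions]
        sol = solve_min_cost(scaled, constraints)
        assert sol.total_cost == pytest.approx(lam * base.total_cost, rel=1e-6)

    def test_adding_a_food_never_increases_cost(self):
        decisions, constraints = four_food_instance()
        base = solve_min_cost(decisions, constraints)
        extra = DecisionSpec(
            item_id="cheap_oil",
            kind=CONTINUOUS_GRAMS,
            bounds=(0.0, 25.0),
            unit_cost=0.006,
            unit_nutrients=NutrientVector({"energy_kcal": 9.0, "fat_g": 1.0}),
            unit_weight=1.0,
            group="edible_oils_and_fats",
        )
        sol = solve_min_cost(decisions + [extra], constraints)
        assert sol.total_cost <= base.total_cost + 1e-9

    def test_lowering_a_unit_cost_never_increases_cost(self):
        from dataclasses import replace

        decisions, constraints = four_food_instance()
        base = solve_min_cost(decisions, constraints)
        cheaper = [
            replace(d, unit_cost=d.unit_cost * (0.5 if d.item_id == "oil" else 1.0))
            for d in decisions
        ]
        sol = solve_min_cost(cheaper, constraints)
        assert sol.total_cost <= base.total_cost + 1e-9

    def test_determinism_identical_inputs_identical_solutions(self):
        decisions, constraints = four_food_instance()
        a = solve_min_cost(decisions, copy.deepcopy(constraints))
        b = solve_min_cost(decisions, copy.deepcopy(constraints))
        assert a.to_dict() == b.to_dict()


class TestKBest:
    def test_k1_equals_min_cost_solution(self):
        decisions, constraints = four_food_instance()
        best = solve_min_cost(decisions, constraints)
        listed = enumerate_k_best(decisions, constraints, k=1)
        assert len(listed) == 1
        assert listed[0].to_dict() == best.to_dict()

    def test_costs_nondecreasing_and_supports_distinct(self):
        decisions, constraints = four_food_instance()
        sols = enumerate_k_best(decisions, constraints, k=5)
        assert len(sols) >= 2
        costs = [s.total_cost for s in sols]
        assert costs == sorted(costs)
        supports = [frozenset(i for i, v in s.selected.items() if v) for s in sols]
        assert len(set(supports)) == len(supports)

    def test_exhausted_supports_shorten_the_list(self):
        cons = ConstraintSet(nutrient_lower={"energy_kcal": 400.0})
        sols = enumerate_k_best(_single_food(), cons, k=5)
        assert len(sols) == 1  # only one possible support

    def test_infeasible_base_gives_empty_list(self):
        cons = ConstraintSet(nutrient_lower={"protein_g": 10.0})
        assert enumerate_k_best(_single_food(), cons, k=3) == []


class TestOracle:
    def test_oracle_matches_closed_form_on_grid(self):
        cons = ConstraintSet(
            nutrient_lower={"energy_kcal": 400.0}, nutrient_upper={"energy_kcal": 400.0}
        )
        oracle = brute_force_oracle(_single_food(), cons, grid_step=1.0)
        milp = solve_min_cost(_single_food(), cons)
        assert oracle.total_cost == pytest.approx(milp.total_cost, rel=1e-9)
        assert oracle.quantities["f"] == 100.0

    def test_empty_feasible_grid_reports_infeasible(self):
        cons = ConstraintSet(nutrient_lower={"protein_g": 50.0})
        oracle = brute_force_oracle(_single_food(), cons, grid_step=10.0)
        assert oracle.status == INFEASIBLE
        assert math.isinf(oracle.total_cost)

    def test_oversized_instance_refused_with_count(self):
        decisions = [
            DecisionSpec(
                item_id=f"f{i}",
                kind=CONTINUOUS_GRAMS,
                bounds=(0.0, 10000.0),
                unit_cost=0.01,
                unit_nutrients=NutrientVector({"energy_kcal": 4.0}),
                unit_weight=1.0,
                group="sugars",
            )
            for i in range(5)
        ]
        with pytest.raises(ModelError, match="combinations"):
            brute_force_oracle(decisions, ConstraintSet(), grid_step=0.01)


class TestChecker:
    def test_checker_flags_injected_violation(self):
        decisions, constraints = four_food_instance()
        sol = solve_min_cost(decisions, constraints)
        broken = copy.deepcopy(sol)
        broken.quantities["oil"] = 0.0  # fat floor now unmet
        violations = check_solution(decisions, constraints, broken)
        assert any("fat" in v or "mismatch" in v for v in violations)

    def test_checker_accepts_true_optimum(self):
        decisions, constraints = four_food_instance()
        sol = solve_min_cost(decisions, constraints)
        assert check_solution(decisions, constraints, sol) == []
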