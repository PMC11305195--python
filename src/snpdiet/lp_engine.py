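"""Mixed-integer linear model construction and solving for least-cost diets.

The model minimizes total cost ``sum_i Q_i * C_i`` over item quantities
``Q_i`` (grams of raw food, or serving multipliers of recipes) subject to
nutrient bounds, food-group inclusion, group/item quantity windows, linear
ratio constraints (e.g. cereal = 2 x pulse), item forcing and an optional
budget.  Selection logic (a group must contribute at least one *selected*
item; semi-continuous serving sizes) is expressed with binary selection
variables ``y_i`` linked to quantities by ``min_i*y_i <= Q_i <= max_i*y_i``.

Solved with the HiGHS solver via :func:`scipy.optimize.milp`.  Also provides
k-best enumeration via no-good cuts on the binary support, an exhaustive
grid-search oracle for verification at toy scale, and an independent post-hoc
constraint checker.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .nutrients import NUTRIENT_FIELDS, NutrientVector

CONTINUOUS_GRAMS = "continuous_grams"
SEMI_CONTINUOUS_SERVINGS = "semi_continuous_servings"

#: Solution status values.
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
OVER_BUDGET = "over_budget"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class DecisionSpec:
    """One decision variable: an item that may enter the ration.

    ``bounds`` are (min, max) in the item's unit — grams for raw foods,
    serving multipliers for recipes.  When the item is selected its quantity
    must lie in [min, max]; when not selected it is exactly 0.
    """

    item_id: str
    kind: str
    bounds: tuple[float, float]
    unit_cost: float
    unit_nutrients: NutrientVector
    unit_weight: float
    group: str
    mode: str = "whole"  # "whole" | "premix"
    selection_required: bool = False

    def __post_init__(self):
        lo, hi = self.bounds
        if lo > hi:
            raise ModelError(f"{self.item_id}: bounds min {lo} > max {hi}")
        if lo < 0:
            raise ModelError(f"{self.item_id}: bounds must be nonnegative")
        if self.unit_cost < 0:
            raise ModelError(f"{self.item_id}: unit_cost must be >= 0")
        if self.kind not in (CONTINUOUS_GRAMS, SEMI_CONTINUOUS_SERVINGS):
            raise ModelError(f"{self.item_id}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class RatioConstraint:
    """|sum_num(weight) - ratio * sum_den(weight)| <= tolerance * ratio * sum_den."""

    name: str
    numerator_groups: tuple[str, ...]
    denominator_groups: tuple[str, ...]
    ratio: float
    tolerance: float = 0.0

    def __post_init__(self):
        if self.ratio <= 0:
            raise ModelError(f"ratio constraint {self.name}: ratio must be > 0")
        if self.tolerance < 0:
            raise ModelError(f"ratio constraint {self.name}: tolerance must be >= 0")


@dataclass
class ConstraintSet:
    """Declarative constraints applied to a set of decisions."""

    nutrient_lower: dict[str, float] = field(default_factory=dict)
    nutrient_upper: dict[str, float] = field(default_factory=dict)
    group_min_count: dict[str, int] = field(default_factory=dict)
    group_max_count: dict[str, int] = field(default_factory=dict)
    # (group, mode) -> (min g, max g); mode "any" covers whole and premix
    quantity_windows: dict[tuple[str, str], tuple[float | None, float | None]] = field(
        default_factory=dict
    )
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    force_select: tuple[str, ...] = ()
    budget: float | None = None
    budget_hard: bool = False

    def __post_init__(self):
        for name in itertools.chain(self.nutrient_lower, self.nutrient_upper):
            if name not in NUTRIENT_FIELDS:
                raise ModelError(f"unknown nutrient in constraint set: {name!r}")


@dataclass
class RationSolution:
    """An optimized ration: quantities, cost, nutrient totals, diagnostics."""

    quantities: dict[str, float]
    selected: dict[str, bool]
    total_cost: float
    nutrient_totals: NutrientVector
    status: str
    binding_constraints: list[str] = field(default_factory=list)
    infeasibility_hint: list[str] = field(default_factory=list)
    best_effort: bool = False
    shortfall: dict[str, float] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.status in (OPTIMAL, OVER_BUDGET)

    def to_dict(self) -> dict:
        return {
            "quantities": dict(sorted(self.quantities.items())),
            "selected": dict(sorted(self.selected.items())),
            "total_cost": self.total_cost,
            "nutrient_totals": self.nutrient_totals.as_dict(),
            "status": self.status,
            "binding_constraints": list(self.binding_constraints),
            "best_effort": self.best_effort,
            "shortfall": dict(sorted(self.shortfall.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RationSolution":
        return cls(
            quantities={k: float(v) for k, v in d["quantities"].items()},
            selected={k: bool(v) for k, v in d.get("selected", {}).items()},
            total_cost=float(d["total_cost"]),
            nutrient_totals=NutrientVector(d["nutrient_totals"]),
            status=d.get("status", OPTIMAL),
            binding_constraints=list(d.get("binding_constraints", [])),
            best_effort=bool(d.get("best_effort", False)),
            shortfall={k: float(v) for k, v in d.get("shortfall", {}).items()},
        )


@dataclass(frozen=True)
class SolverConfig:
    mip_gap: float = 1e-6
    feasibility_tol: float = 1e-7
    time_limit_s: float | None = None
    compute_hints: bool = True


# ---------------------------------------------------------------------------
# Model construction

def _window_applies(window_mode: str, decision_mode: str) -> bool:
    return window_mode == "any" or window_mode == decision_mode


def _build_rows(
    decisions: list[DecisionSpec], constraints: ConstraintSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Linear rows over variables [q_0..q_{n-1}, y_0..y_{n-1}].

    Returns (A, lb, ub, names, families).
    """
    n = len(decisions)
    rows, lbs, ubs, names, families = [], [], [], [], []

    def add(coeffs, lb, ub, name, family):
        rows.append(coeffs)
        lbs.append(lb)
        ubs.append(ub)
        names.append(name)
        families.append(family)

    # Linking: min*y <= q <= max*y
    for i, d in enumerate(decisions):
        lo, hi = d.bounds
        if lo > 0:
            r = np.zeros(2 * n)
            r[i] = 1.0
            r[n + i] = -lo
            add(r, 0.0, np.inf, f"link_min[{d.item_id}]", "item_minimums")
        r = np.zeros(2 * n)
        r[i] = 1.0
        r[n + i] = -hi
        add(r, -np.inf, 0.0, f"link_max[{d.item_id}]", "item_maximums")

    # Nutrient bounds
    nmat = np.stack([d.unit_nutrients.values for d in decisions])  # (n, 16)
    for k, nut in enumerate(NUTRIENT_FIELDS):
        lo = constraints.nutrient_lower.get(nut)
        hi = constraints.nutrient_upper.get(nut)
        if lo is None and hi is None:
            continue
        r = np.zeros(2 * n)
        r[:n] = nmat[:, k]
        if lo is not None and hi is not None:
            add(r, lo, hi, f"nutrient[{nut}]", "nutrient_lower")
        elif lo is not None:
            add(r, lo, np.inf, f"nutrient_lower[{nut}]", "nutrient_lower")
        else:
            add(r, -np.inf, hi, f"nutrient_upper[{nut}]", "nutrient_upper")

    # Group inclusion counts (on binaries)
    groups = {d.group for d in decisions}
    for g, cmin in constraints.group_min_count.items():
        r = np.zeros(2 * n)
        for i, d in enumerate(decisions):
            if d.group == g:
                r[n + i] = 1.0
        cmax = constraints.group_max_count.get(g)
        add(r, float(cmin), np.inf if cmax is None else float(cmax),
            f"group_count[{g}]", "group_inclusion")
    for g, cmax in constraints.group_max_count.items():
        if g in constraints.group_min_count:
            continue
        r = np.zeros(2 * n)
        for i, d in enumerate(decisions):
            if d.group == g:
                r[n + i] = 1.0
        add(r, 0.0, float(cmax), f"group_count[{g}]", "group_inclusion")
    del groups

    # Group quantity windows (grams of raw weight)
    for (g, mode), (wlo, whi) in constraints.quantity_windows.items():
        r = np.zeros(2 * n)
        for i, d in enumerate(decisions):
            if d.group == g and _window_applies(mode, d.mode):
                r[i] = d.unit_weight
        add(
            r,
            -np.inf if wlo is None else float(wlo),
            np.inf if whi is None else float(whi),
            f"group_window[{g},{mode}]",
            "group_windows",
        )

    # Ratio constraints: num - ratio(1 +/- tol) * den <=/>= 0
    for rc in constraints.ratio_constraints:
        num = np.zeros(n)
        den = np.zeros(n)
        for i, d in enumerate(decisions):
            if d.group in rc.numerator_groups:
                num[i] = d.unit_weight
            if d.group in rc.denominator_groups:
                den[i] = d.unit_weight
        r_hi = np.zeros(2 * n)
        r_hi[:n] = num - rc.ratio * (1.0 + rc.tolerance) * den
        add(r_hi, -np.inf, 0.0, f"ratio_high[{rc.name}]", "ratio")
        r_lo = np.zeros(2 * n)
        r_lo[:n] = num - rc.ratio * (1.0 - rc.tolerance) * den
        add(r_lo, 0.0, np.inf, f"ratio_low[{rc.name}]", "ratio")

    # Forcing
    ids = {d.item_id: i for i, d in enumerate(decisions)}
    for item in constraints.force_select:
        if item not in ids:
            raise ModelError(f"force_select references unknown item {item!r}")
        r = np.zeros(2 * n)
        r[n + ids[item]] = 1.0
        add(r, 1.0, 1.0, f"force[{item}]", "forcing")

    # Hard budget
    if constraints.budget is not None and constraints.budget_hard:
        r = np.zeros(2 * n)
        r[:n] = [d.unit_cost for d in decisions]
        add(r, -np.inf, float(constraints.budget), "budget", "budget")

    A = np.array(rows) if rows else np.zeros((0, 2 * n))
    return A, np.array(lbs), np.array(ubs), names, families


def _recompute(decisions: list[DecisionSpec], q: np.ndarray) -> tuple[float, NutrientVector]:
    cost = float(sum(d.unit_cost * qi for d, qi in zip(decisions, q)))
    totals = np.zeros(len(NUTRIENT_FIELDS))
    for d, qi in zip(decisions, q):
        totals += qi * d.unit_nutrients.values
    return cost, NutrientVector(np.maximum(totals, 0.0))


def _solve_milp(
    decisions: list[DecisionSpec],
    constraints: ConstraintSet,
    config: SolverConfig,
    extra_rows: list[tuple[np.ndarray, float, float]] | None = None,
):
    """Low-level solve.  Returns (q, y, A, lb, ub, names) or None if infeasible."""
    n = len(decisions)
    A, lb, ub, names, _families = _build_rows(decisions, constraints)
    if extra_rows:
        A = np.vstack([A] + [r for r, _, _ in extra_rows]) if len(A) else np.stack(
            [r for r, _, _ in extra_rows]
        )
        lb = np.concatenate([lb, [l for _, l, _ in extra_rows]])
        ub = np.concatenate([ub, [u for _, _, u in extra_rows]])
        names = names + [f"cut[{i}]" for i in range(len(extra_rows))]

    c = np.zeros(2 * n)
    c[:n] = [d.unit_cost for d in decisions]
    var_lb = np.zeros(2 * n)
    var_ub = np.empty(2 * n)
    integrality = np.zeros(2 * n)
    for i, d in enumerate(decisions):
        var_ub[i] = d.bounds[1]
        var_ub[n + i] = 1.0
        var_lb[n + i] = 1.0 if d.selection_required else 0.0
        integrality[n + i] = 1
    options = {"mip_rel_gap": config.mip_gap, "presolve": True}
    if config.time_limit_s is not None:
        options["time_limit"] = config.time_limit_s
    cons = [LinearConstraint(A, lb, ub)] if len(A) else []
    res = milp(
        c,
        constraints=cons,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options=options,
    )
    if res.status != 0 or res.x is None:
        return None
    x = np.asarray(res.x)
    q = x[:n].copy()
    y = x[n:] > 0.5
    q[~y] = 0.0
    q[np.abs(q) < 1e-9] = 0.0
    return q, y, A, lb, ub, names


def _finish_solution(
    decisions: list[DecisionSpec],
    constraints: ConstraintSet,
    q: np.ndarray,
    y: np.ndarray,
    A: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    names: list[str],
) -> RationSolution:
    n = len(decisions)
    cost, totals = _recompute(decisions, q)
    x = np.concatenate([q, y.astype(float)])
    binding = []
    if len(A):
        act = A @ x
        for j, name in enumerate(names):
            tol = 1e-6 * max(1.0, abs(act[j]))
            if (np.isfinite(lb[j]) and abs(act[j] - lb[j]) <= tol) or (
                np.isfinite(ub[j]) and abs(act[j] - ub[j]) <= tol
            ):
                if not name.startswith(("link_", "cut[")):
                    binding.append(name)
    status = OPTIMAL
    if constraints.budget is not None and cost > constraints.budget * (1 + 1e-9):
        status = OVER_BUDGET
    return RationSolution(
        quantities={d.item_id: float(q[i]) for i, d in enumerate(decisions)},
        selected={d.item_id: bool(y[i]) for i, d in enumerate(decisions)},
        total_cost=cost,
        nutrient_totals=totals,
        status=status,
        binding_constraints=binding,
    )


_RELAXATIONS = (
    "nutrient_lower",
    "nutrient_upper",
    "group_inclusion",
    "group_windows",
    "ratio",
    "forcing",
    "item_minimums",
    "budget",
)


def _relax_family(
    decisions: list[DecisionSpec], constraints: ConstraintSet, family: str
) -> tuple[list[DecisionSpec], ConstraintSet]:
    cs = replace(
        constraints,
        nutrient_lower=dict(constraints.nutrient_lower),
        nutrient_upper=dict(constraints.nutrient_upper),
        group_min_count=dict(constraints.group_min_count),
        group_max_count=dict(constraints.group_max_count),
        quantity_windows=dict(constraints.quantity_windows),
        ratio_constraints=list(constraints.ratio_constraints),
    )
    ds = decisions
    if family == "nutrient_lower":
        cs.nutrient_lower = {}
    elif family == "nutrient_upper":
        cs.nutrient_upper = {}
    elif family == "group_inclusion":
        cs.group_min_count = {}
        cs.group_max_count = {}
    elif family == "group_windows":
        cs.quantity_windows = {}
    elif family == "ratio":
        cs.ratio_constraints = []
    elif family == "forcing":
        cs.force_select = ()
    elif family == "item_minimums":
        ds = [replace(d, bounds=(0.0, d.bounds[1])) for d in decisions]
    elif family == "budget":
        cs.budget_hard = False
    return ds, cs


def _infeasibility_hint(
    decisions: list[DecisionSpec], constraints: ConstraintSet, config: SolverConfig
) -> list[str]:
    """Constraint families whose removal (one at a time) restores feasibility."""
    hints = []
    for family in _RELAXATIONS:
        if family == "budget" and not (constraints.budget_hard and constraints.budget is not None):
            continue
        ds, cs = _relax_family(decisions, constraints, family)
        probe = replace(config, compute_hints=False)
        if _solve_milp(ds, cs, probe) is not None:
            hints.append(family)
    return hints


def solve_min_cost(
    decisions: list[DecisionSpec],
    constraints: ConstraintSet,
    config: SolverConfig | None = None,
) -> RationSolution:
    """Solve the least-cost ration MILP.

    Deterministic for fixed inputs: decisions are ordered lexicographically by
    item id before model construction and HiGHS runs single-threaded here.
    """
    if not decisions:
        raise ModelError("at least one decision is required")
    seen = set()
    for d in decisions:
        if d.item_id in seen:
            raise ModelError(f"duplicate decision item id {d.item_id!r}")
        seen.add(d.item_id)
    config = config or SolverConfig()
    decisions = sorted(decisions, key=lambda d: d.item_id)
    out = _solve_milp(decisions, constraints, config)
    if out is None:
        hint = _infeasibility_hint(decisions, constraints, config) if config.compute_hints else []
        return RationSolution(
            quantities={d.item_id: 0.0 for d in decisions},
            selected={d.item_id: False for d in decisions},
            total_cost=math.inf,
            nutrient_totals=NutrientVector(),
            status=INFEASIBLE,
            infeasibility_hint=hint,
        )
    return _finish_solution(decisions, constraints, *out)


def enumerate_k_best(
    decisions: list[DecisionSpec],
    constraints: ConstraintSet,
    k: int,
    config: SolverConfig | None = None,
) -> list[RationSolution]:
    """k cheapest solutions with pairwise-distinct selected-item supports.

    Uses no-good cuts on the binary support: after finding support S, the cut
    ``sum_{i in S} y_i - sum_{i not in S} y_i <= |S| - 1`` excludes exactly S
    while leaving every other support available.  Costs are nondecreasing.
    The list may be shorter than k when supports are exhausted.
    """
    if k < 1:
        raise ModelError("k must be >= 1")
    config = config or SolverConfig()
    decisions = sorted(decisions, key=lambda d: d.item_id)
    n = len(decisions)
    cuts: list[tuple[np.ndarray, float, float]] = []
    solutions: list[RationSolution] = []
    for _ in range(k):
        out = _solve_milp(decisions, constraints, config, extra_rows=cuts)
        if out is None:
            break
        q, y, A, lb, ub, names = out
        solutions.append(_finish_solution(decisions, constraints, q, y, A, lb, ub, names))
        row = np.zeros(2 * n)
        row[n:] = np.where(y, 1.0, -1.0)
        cuts.append((row, -np.inf, float(y.sum()) - 1.0))
    return solutions


# ---------------------------------------------------------------------------
# Post-hoc constraint checker (independent of the matrix construction above)

def check_solution(
    decisions: list[DecisionSpec],
    constraints: ConstraintSet,
    solution: RationSolution,
    rtol: float = 1e-6,
) -> list[str]:
    """Re-evaluate every constraint from raw decision data; return violations."""
    viol: list[str] = []
    by_id = {d.item_id: d for d in decisions}
    q = {d.item_id: solution.quantities.get(d.item_id, 0.0) for d in decisions}
    sel = {d.item_id: solution.selected.get(d.item_id, False) for d in decisions}

    def slack(bound):
        return rtol * max(1.0, abs(bound))

    for d in decisions:
        qi, yi = q[d.item_id], sel[d.item_id]
        if not yi and abs(qi) > 1e-9:
            viol.append(f"{d.item_id}: unselected but quantity {qi}")
        if yi:
            lo, hi = d.bounds
            if qi < lo - slack(lo) or qi > hi + slack(hi):
                viol.append(f"{d.item_id}: quantity {qi} outside bounds [{lo}, {hi}]")
        if d.selection_required and not yi:
            viol.append(f"{d.item_id}: selection required but not selected")

    totals = {nut: 0.0 for nut in NUTRIENT_FIELDS}
    cost = 0.0
    for d in decisions:
        for nut in NUTRIENT_FIELDS:
            totals[nut] += q[d.item_id] * d.unit_nutrients[nut]
        cost += q[d.item_id] * d.unit_cost
    for nut, lo in constraints.nutrient_lower.items():
        if totals[nut] < lo - slack(lo):
            viol.append(f"nutrient_lower[{nut}]: {totals[nut]} < {lo}")
    for nut, hi in constraints.nutrient_upper.items():
        if totals[nut] > hi + slack(hi):
            viol.append(f"nutrient_upper[{nut}]: {totals[nut]} > {hi}")

    for g, cmin in constraints.group_min_count.items():
        count = sum(1 for d in decisions if d.group == g and sel[d.item_id])
        if count < cmin:
            viol.append(f"group_count[{g}]: {count} < {cmin}")
    for g, cmax in constraints.group_max_count.items():
        count = sum(1 for d in decisions if d.group == g and sel[d.item_id])
        if count > cmax:
            viol.append(f"group_count[{g}]: {count} > {cmax}")

    for (g, mode), (wlo, whi) in constraints.quantity_windows.items():
        w = sum(
            q[d.item_id] * d.unit_weight
            for d in decisions
            if d.group == g and _window_applies(mode, d.mode)
        )
        if wlo is not None and w < wlo - slack(wlo):
            viol.append(f"group_window[{g},{mode}]: {w} < {wlo}")
        if whi is not None and w > whi + slack(whi):
            viol.append(f"group_window[{g},{mode}]: {w} > {whi}")

    for rc in constraints.ratio_constraints:
        num = sum(
            q[d.item_id] * d.unit_weight for d in decisions if d.group in rc.numerator_groups
        )
        den = sum(
            q[d.item_id] * d.unit_weight for d in decisions if d.group in rc.denominator_groups
        )
        dev = abs(num - rc.ratio * den)
        allowed = rc.tolerance * rc.ratio * den + rtol * max(1.0, rc.ratio * den)
        if dev > allowed:
            viol.append(f"ratio[{rc.name}]: |{num} - {rc.ratio}*{den}| = {dev} > {allowed}")

    for item in constraints.force_select:
        if item in by_id and not sel[item]:
            viol.append(f"force[{item}]: not selected")

    if constraints.budget is not None and constraints.budget_hard:
        if cost > constraints.budget + slack(constraints.budget):
            viol.append(f"budget: {cost} > {constraints.budget}")

    # internal consistency of the solution record
    if math.isfinite(solution.total_cost):
        if abs(cost - solution.total_cost) > rtol * max(1.0, abs(cost)):
            viol.append(f"total_cost mismatch: recorded {solution.total_cost}, recomputed {cost}")
        for nut in NUTRIENT_FIELDS:
            rec = solution.nutrient_totals[nut]
            if abs(rec - totals[nut]) > rtol * max(1.0, abs(totals[nut])):
                viol.append(f"nutrient_totals[{nut}] mismatch: {rec} vs {totals[nut]}")
    return viol


# ---------------------------------------------------------------------------
# Brute-force grid oracle

MAX_GRID_COMBINATIONS = 10_000_000


def brute_force_oracle(
    decisions: list[DecisionSpec],
    constraints: ConstraintSet,
    grid_step: float,
) -> RationSolution:
    """Exact optimum over a quantity grid; verification use only.

    Each decision's grid is {0} union {min, min+step, ..., max} (0 omitted
    when selection is required or the item is forced).  Refuses instances with
    more than 1e7 grid combinations or more than 6 decisions.
    """
    if len(decisions) > 6:
        raise ModelError(f"oracle limited to 6 decisions, got {len(decisions)}")
    decisions = sorted(decisions, key=lambda d: d.item_id)
    forced = set(constraints.force_select)
    grids: list[np.ndarray] = []
    for d in decisions:
        lo, hi = d.bounds
        pts = np.arange(lo, hi + grid_step * 1e-9, grid_step)
        if len(pts) == 0 or pts[-1] < hi - 1e-12:
            pts = np.append(pts, hi)
        if not (d.selection_required or d.item_id in forced):
            pts = np.concatenate([[0.0], pts]) if lo > 0 or pts[0] != 0 else pts
        grids.append(np.unique(pts))
    total = math.prod(len(g) for g in grids)
    if total > MAX_GRID_COMBINATIONS:
        raise ModelError(
            f"grid too large: {total} combinations exceed {MAX_GRID_COMBINATIONS}"
        )

    # Split into head (python loop) and tail (vectorized cartesian block).
    tail_size = 1
    split = len(decisions)
    while split > 0 and tail_size * len(grids[split - 1]) <= 20000:
        tail_size *= len(grids[split - 1])
        split -= 1
    head_grids, tail_grids = grids[:split], grids[split:]
    tail_decisions = decisions[split:]
    if tail_grids:
        mesh = np.meshgrid(*tail_grids, indexing="ij")
        Qtail = np.stack([m.ravel() for m in mesh], axis=1)  # (T, n_tail)
    else:
        Qtail = np.zeros((1, 0))
    T = Qtail.shape[0]

    tail_cost = Qtail @ np.array([d.unit_cost for d in tail_decisions]) if tail_decisions else np.zeros(T)
    nmat_tail = (
        np.stack([d.unit_nutrients.values for d in tail_decisions])
        if tail_decisions
        else np.zeros((0, len(NUTRIENT_FIELDS)))
    )
    tail_nut = Qtail @ nmat_tail  # (T, 16)
    tail_sel = Qtail > 1e-12

    head_decisions = decisions[:split]
    nmat_head = (
        np.stack([d.unit_nutrients.values for d in head_decisions])
        if head_decisions
        else np.zeros((0, len(NUTRIENT_FIELDS)))
    )
    cost_head = np.array([d.unit_cost for d in head_decisions])

    nut_idx = {nut: i for i, nut in enumerate(NUTRIENT_FIELDS)}

    def group_weight_vec(sub_decisions, Q, pred):
        w = np.array([d.unit_weight if pred(d) else 0.0 for d in sub_decisions])
        return Q @ w if len(sub_decisions) else np.zeros(Q.shape[0])

    best_cost = math.inf
    best_q: np.ndarray | None = None
    iterator = itertools.product(*head_grids) if head_grids else [()]
    for head in iterator:
        hq = np.asarray(head, dtype=float)
        cost = tail_cost + (hq @ cost_head if len(hq) else 0.0)
        mask = np.ones(T, dtype=bool)
        nut_tot = tail_nut + (hq @ nmat_head if len(hq) else 0.0)
        for nut, lo in constraints.nutrient_lower.items():
            mask &= nut_tot[:, nut_idx[nut]] >= lo - 1e-9
        for nut, hi in constraints.nutrient_upper.items():
            mask &= nut_tot[:, nut_idx[nut]] <= hi + 1e-9
        if not mask.any():
            continue
        hsel = hq > 1e-12
        for g, cmin in constraints.group_min_count.items():
            head_count = sum(
                1 for d, s in zip(head_decisions, hsel) if d.group == g and s
            )
            tcols = [j for j, d in enumerate(tail_decisions) if d.group == g]
            counts = head_count + (tail_sel[:, tcols].sum(axis=1) if tcols else 0)
            mask &= counts >= cmin
        for g, cmax in constraints.group_max_count.items():
            head_count = sum(
                1 for d, s in zip(head_decisions, hsel) if d.group == g and s
            )
            tcols = [j for j, d in enumerate(tail_decisions) if d.group == g]
            counts = head_count + (tail_sel[:, tcols].sum(axis=1) if tcols else 0)
            mask &= counts <= cmax
        for (g, mode), (wlo, whi) in constraints.quantity_windows.items():
            pred = lambda d, g=g, mode=mode: d.group == g and _window_applies(mode, d.mode)
            w = group_weight_vec(tail_decisions, Qtail, pred) + float(
                sum(qi * d.unit_weight for qi, d in zip(hq, head_decisions) if pred(d))
            )
            if wlo is not None:
                mask &= w >= wlo - 1e-9
            if whi is not None:
                mask &= w <= whi + 1e-9
        for rc in constraints.ratio_constraints:
            npred = lambda d, rc=rc: d.group in rc.numerator_groups
            dpred = lambda d, rc=rc: d.group in rc.denominator_groups
            num = group_weight_vec(tail_decisions, Qtail, npred) + float(
                sum(qi * d.unit_weight for qi, d in zip(hq, head_decisions) if npred(d))
            )
            den = group_weight_vec(tail_decisions, Qtail, dpred) + float(
                sum(qi * d.unit_weight for qi, d in zip(hq, head_decisions) if dpred(d))
            )
            mask &= np.abs(num - rc.ratio * den) <= rc.tolerance * rc.ratio * den + 1e-9
        if constraints.budget is not None and constraints.budget_hard:
            mask &= cost <= constraints.budget + 1e-9
        if not mask.any():
            continue
        masked_cost = np.where(mask, cost, math.inf)
        j = int(np.argmin(masked_cost))
        if masked_cost[j] < best_cost:
            best_cost = float(masked_cost[j])
            best_q = np.concatenate([hq, Qtail[j]])

    if best_q is None:
        return RationSolution(
            quantities={d.item_id: 0.0 for d in decisions},
            selected={d.item_id: False for d in decisions},
            total_cost=math.inf,
            nutrient_totals=NutrientVector(),
            status=INFEASIBLE,
        )
    cost, totals = _recompute(decisions, best_q)
    status = OPTIMAL
    if constraints.budget is not None and cost > constraints.budget * (1 + 1e-9):
        status = OVER_BUDGET
    return RationSolution(
        quantities={d.item_id: float(v) for d, v in zip(decisions, best_q)},
        selected={d.item_id: bool(v > 1e-12) for d, v in zip(decisions, best_q)},
        total_cost=cost,
        nutrient_totals=totals,
        status=status,
    )
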