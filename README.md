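# snpdiet

Least-cost diet formulation for supplementary nutrition programs (SNPs), such
as India's Integrated Child Development Services, built for the people who
decide what goes into a take-home ration (THR) or onto an *Anganwadi* lunch
plate: program implementers, nutritionists and policy analysts.

Large feeding programs must compose, from locally available foods and at a
fixed budget (₹8 per child per day in the Indian case), provisions that meet
per-beneficiary nutrient rules — e.g. 400 kcal with 15 g protein and 15 g fat
per day for a 1–3 year old. `snpdiet` formulates this as a mixed-integer
linear program and solves it exactly:

```
minimize    Σᵢ Qᵢ · Cᵢ
subject to  L_k ≤ Σᵢ Qᵢ · aᵢₖ ≤ U_k          (nutrient bands / upper limits)
            Σ_{i∈g} yᵢ ≥ 1                    (≥1 food per mandatory group)
            (1−τ)·2·Σ_pulse Qᵢ ≤ Σ_cereal Qᵢ ≤ (1+τ)·2·Σ_pulse Qᵢ
            minᵢ·yᵢ ≤ Qᵢ ≤ maxᵢ·yᵢ,  yᵢ ∈ {0,1}
```

where `Qᵢ` is grams of raw food *i* (THR) or the serving multiplier of recipe
*i* (hot cooked meal, HCM) and `Cᵢ` its unit cost; `aᵢₖ` is the per-unit
amount of nutrient *k*. Semi-continuous serving sizes, compulsory items
(egg/milk recipes, a required cereal or millet), per-item quantity windows,
subsidized prices and fortification overlays are all first-class. When the
optimum exceeds the budget, the engine enumerates the next least expensive
food combinations (k-best, via no-good cuts on the selection support), so
users can trade diversity against cost.

Sixteen nutrients are tracked (energy, protein, fat, fiber, Ca, Zn, Fe, Mg,
vitamins A, B1, B2, B3, B6, B12, C, folate). Guideline sets per beneficiary
category (children 6 mo–6 y, severely acutely malnourished children, pregnant
and lactating women) are packaged and user-editable; adequacy analytics
reproduce the program tooling's percent-of-guideline tables, color-coded
adequacy, food-group doughnut and radar-ratio charts as structured data.

## Worked example

```python
from snpdiet import default_guidelines, optimize_thr, THRConfig, percent_of_guideline
from snpdiet.fixtures import toy_instances

toy = toy_instances()["thr_toy_5"]          # 5 synthetic foods, printed in-module
gl = default_guidelines("child_1_3y")       # 400 kcal / 15 g protein / 15 g fat
sol = optimize_thr(toy["db"], gl, toy["config"])[0]
print(sol.status, round(sol.total_cost, 4))
print({k: round(v, 1) for k, v in sol.quantities.items() if v > 0})
print({r.nutrient: r.percent for r in percent_of_guideline(sol.nutrient_totals, gl)[:3]})
```

prints

```
optimal 0.8427
{'green_gram': 22.8, 'milk_powder': 15.6, 'rice': 44.6, 'sugar': 5.0, 'sunflower_oil': 8.5}
{'energy_kcal': 102.0, 'protein_g': 90.0, 'fat_g': 90.0}
```

i.e. the cheapest daily ration costs 0.8427 currency units, holds a 2:1
cereal:pulse mass ratio (44.6 ≈ 2 × 22.8), includes all four mandatory food
groups, and sits at the edges of the macro bands (energy at 102 % of target,
protein and fat at the 90 % floor) — exactly where a cost minimizer should.

The same flows are available from a shell:

```sh
snpdiet fixtures generate --seed 3 --mode feasible --out fx/
snpdiet thr --db fx/foods.csv --category child_1_3y --budget 8 --out run/
snpdiet hcm --db fx/database.json --category child_3_6y \
    --select main_cereal_1,main_cereal_2,curry_pulse,curry_tuber,side_salad \
    --compulsory boiled_egg --days 6 --out menu/
```

Exit codes: 0 success, 2 invalid input, 3 infeasible model (the log names the
constraint families whose relaxation restores feasibility).

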