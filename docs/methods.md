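# Methods

## The optimization model

Both product types minimize total daily cost `Σᵢ Qᵢ·Cᵢ` over a user-chosen
pool of items. For a take-home ration (THR) the decision `Qᵢ` is grams of raw
food *i* per day and `Cᵢ` its effective price per gram (retail or subsidized,
per-kg prices divided by 1000). For a hot cooked meal (HCM) the decision is a
serving multiplier per recipe and `Cᵢ` the derived cost of one serving
(ingredient grams × per-gram prices, recomputed on demand and never cached).

Selection logic is encoded with one binary `yᵢ` per item, linked by
`minᵢ·yᵢ ≤ Qᵢ ≤ maxᵢ·yᵢ`. This makes quantities semi-continuous — an item is
either absent or present at a meaningful level — which is what gives
group-inclusion constraints ("at least one cereal, pulse, sugar and oil")
their intended meaning: a group is only *covered* by an item actually served.
The model is therefore a mixed-integer LP, not a pure LP, and is solved with
the HiGHS branch-and-bound solver through `scipy.optimize.milp` (relative MIP
gap 1e-6, single-threaded, decisions ordered lexicographically by item id for
determinism).

Constraint families, all expressed as linear rows:

- **Nutrient bands.** Macronutrient targets are enforced as bands around the
  guideline value: energy (1.00, 1.02)×target, protein and fat
  (0.90, 1.35)×target by default. The asymmetric defaults reflect how
  program menus actually behave — energy is pinned essentially at target
  while protein overshoots and fat dips to ~90 % — and, mechanically, a strict
  ≥100 % rule on all three macros at once is unattainable with ordinary food
  matrices (see "Why the dense food matters" below). Micronutrients are
  *reported against* their guideline values rather than enforced, matching
  program practice where a meal may be accepted at 5 % of the vitamin C
  value; an opt-in set (`THRConfig.enforce_micros`) turns any subset into
  hard lower bounds. Tolerable upper limits, where supplied, become upper
  bounds. A target of 0 means "unconstrained below", never "force zero".
- **Group inclusion.** Minimum (and for recipe categories also maximum)
  counts of selected items per group, on the binaries.
- **Cereal:pulse ratio.** `|Σ_cereal − r·Σ_pulse| ≤ τ·r·Σ_pulse` with r=2,
  τ=0.02, linearized as two inequalities. Premix-eligible foods count toward
  the ratio like any other raw grams.
- **Quantity windows.** Per-group (whole vs premix mode) gram windows and
  per-item windows. Restricted item classes get tight default windows per
  day: oils 5–15 g, sugars/jaggery 5–30 g, nuts and seeds 5–20 g, milk powder
  5–40 g, egg 25–50 g; anything else 5–250 g. The 5 g floor is what makes
  "selected" nontrivial.
- **Forcing.** Compulsory items (a required cereal/millet in a THR; egg,
  milk or milk-powder recipes in an HCM) have `yᵢ = 1`.
- **Budget.** Soft by default: the optimum is still reported, flagged
  `over_budget`, mirroring how a ₹9.6 optimum against a ₹8 budget is a
  finding, not an error. `budget_hard=True` adds the cap as a constraint.

Infeasible models return a relaxation hint: each constraint family is dropped
in turn and the families whose removal restores feasibility are listed.

**k-best enumeration.** Alternatives are generated by re-solving with a
no-good cut on the previous binary support
(`Σ_{i∈S} yᵢ − Σ_{i∉S} yᵢ ≤ |S|−1`), so successive solutions differ in
*which* items are used, not merely in quantities; costs are nondecreasing by
construction.

**HCM specifics.** Default category structure: exactly 1 main dish, exactly
1 curry, ≤1 side dish, ≤2 additional items, no snacks in the base meal; all
configurable. A selected recipe's multiplier lies in [α, 1.5] with α = 0.5 by
default — the lower fraction of the predetermined serving size is a genuine
design gap, documented as such and configurable. Compulsory recipes are
exempted from category counting (they are forced in regardless of their
nominal category).

**SAM augmentation.** For severe-acute-malnutrition categories the accepted
meal is augmented rather than re-optimized: the search enumerates adding one
snack, two snacks, scaling all multipliers uniformly (grid of 0.05 steps up
to a 1.25× cap, each multiplier clipped at the 1.5 serving ceiling), and
their combinations; among configurations meeting the elevated macro floors
the cheapest (then fewest-snack) wins. If nothing suffices, the
highest-energy configuration is returned with an explicit per-nutrient
shortfall — never silently. Snacks-before-scaling is a preference ordering
only; the cost criterion decides among qualifying combinations.

**Weekly menus.** Days are optimized independently and assembled (users
combine or repeat suggested meals); the menu reports mean and sample standard
deviation (n−1) of daily cost and per-day macro series with protein:energy
and fat:energy as percent of energy via Atwater factors 4 and 9 kcal/g.
Cost extrapolations use 7/30/365 days for week/month/year.

## Data model and conventions

Nutrients are stored per 100 g edible portion (food-composition-table
convention); 16 fixed fields with units in the names. Prices are per kg with
an uninterpreted currency label. Fortification is an additive per-100 g
overlay with global and per-food toggles. Missing nutrient values in CSV
input load as 0 with a logged warning — composition tables are sparse, and
zero is conservative for lower-bound constraints. Percent-of-guideline values
round to one decimal, half away from zero (the tables' printing convention);
radar ratios are unrounded. Adequacy colors: HCM rule green >60 %, red <30 %;
THR rule green >80 %, red <50 %; boundary values fall to orange (the captions
define green and red with strict inequalities).

The packaged guideline matrix maps the published macro table to categories as
child {6–12 mo, 1–3 y, 3–6 y} = (200, 400, 400) kcal, SAM child = (400, 700,
800) kcal, protein (8, 15, 15)/(15, 25, 25) g, fat (10, 15, 15)/(15, 25, 25)
g, pregnant and lactating women (600, 22, 22); the source table's age header
is ambiguous and this alignment is forced by the row value counts.
Micronutrient guideline values are packaged for the 1–3 y and 3–6 y child
categories (several flagged as one-third of the estimated average
requirement, i.e. a single-meal share); other categories carry macros only
until users supply values. Tolerable upper limits ship empty.

## Verification

Two independent oracles check the solver. A brute-force grid search
enumerates `{0} ∪ {min, min+δ, …, max}` per item (vectorized over a tail
block, ≤1e7 combinations, ≤6 items) and yields the exact grid optimum: the
MILP cost must satisfy `oracle − maxᵢCᵢ·δ·n ≤ milp ≤ oracle`. For meals, a
support-enumeration oracle solves a pure LP per admissible recipe
combination. A post-hoc checker re-evaluates every constraint from raw data
(independently of the model matrix) with 1e-6 relative slack. Property tests
cover price scaling, subsidy and food-set monotonicity, k-best ordering and
support distinctness, and byte-level determinism of serialized solutions
(sorted keys, 6-significant-digit floats).

## Synthetic data

The fixture generator draws per-group nutrient densities and prices from
plausible composition-table-like ranges (cereals ≈ 320–360 kcal/100 g with
7–12 g protein, pulses 20–25 g protein, oils ≈ pure fat, milk powder
≈ 500 kcal with ~26 g protein and ~26 g fat, …) under a seeded generator.
`guaranteed_feasible` databases are certified by actually solving the default
THR (child 1–3 y) and HCM (child 3–6 y, compulsory egg) models, with bounded
retries. `guaranteed_infeasible` databases cap every food's fat:energy
density at 0.03 g/kcal, which proves infeasibility analytically: fat intake
≤ 0.03 × 408 kcal ceiling = 12.24 g < the 13.5 g fat floor, no solve needed.

**Why the dense food matters.** With the default bands, a 2:1 cereal:pulse
blend supplies at most ~0.040 g protein per kcal and oil supplies fat at
9 kcal/g, so reaching 13.5 g protein *and* 13.5 g fat within 408 kcal is
impossible from the four mandatory groups alone (the blend plus oil needs
≥ ~455 kcal). A protein-and-fat-dense food outside those groups — milk powder
in the toys and generated fixtures — is load-bearing, and the generator
always includes one in feasible mode.

What the synthetic data does **not** emulate: real regional food lists,
market price structure and seasonality, inter-nutrient correlations within a
food, cooking losses (10–60 % for vitamins depending on method — deliberately
out of scope), or recipe palatability. Passing tests therefore demonstrate
correctness of the optimization and reporting machinery, not nutritional
conclusions about any real program; real analyses require users' own food
and price tables.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale instances: 4–5 food grid-oracle
instances at 1 g resolution with windows sized to keep the grid ≤ ~4e6
combinations, 50 generated feasible databases (10 foods, 7 recipes each), and
6-day menus. MIP relative gap 1e-6, feasibility tolerance 1e-7; quantities
below 1e-9 are snapped to zero; binding constraints are detected at 1e-6
relative slack; ties between equally cheap solutions are stabilized by
lexicographic item ordering. Costs and nutrient totals in a returned solution
are always recomputed from the raw data rather than read off the solver.

## Known limitations

- Micronutrient adequacy is reported, not guaranteed, unless explicitly
  enforced; enforcing many micros at once frequently yields infeasibility on
  small food pools.
- The SAM augmentation is a bounded local search around an accepted meal, not
  a re-optimization; it inherits the base meal's recipe support.
- k-best alternatives differ in support only; equally-supported quantity
  alternatives (degenerate optima) are not enumerated.
- Days of a weekly menu are optimized independently; no joint weekly
  variety constraint exists.
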