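# Methods

This note documents the models implemented in `nutriga`, the parameters that
matter, the numerical conventions, and the design choices made where the
design was genuinely open.

## Energy accounting

Meal energy uses the general Atwater factors — 4 kcal/g for protein and
carbohydrate, 9 kcal/g for fat — applied to per-100 g composition records
and scaled by the household serving factor `f = q/100` (the "food atlas"
weight `q` in grams) and the serving count `N`:

    Z = Σ_k N_k · f_k · (4 p_k + 4 c_k + 9 h_k)

Fibre and alcohol Atwater terms are deliberately out of scope: the engine
models only the three macronutrients it budgets.

Energy is additive over meal concatenation and homogeneous of degree one in
both `N` and `q`; both properties are enforced by tests. Internal arithmetic
is unrounded; values are rounded to 2 decimals only at reporting boundaries.

**Per-serving records.** Real composition tables are not always
Atwater-consistent: composite dishes (waakye, banku, shito, ...) and drinks
are often published only as per-serving calories and macro grams, and a few
per-100 g records come with printed serving energies that the macros do not
reproduce. A serving measure may therefore carry an explicit per-serving
record; when present, its energy (and macros, when given) takes precedence
over the Atwater computation for that measure. The built-in fixture uses
this for the composite dishes and for the three foods whose published
serving energies are not reproducible from their macros (rice ball, rabbit,
smoked tuna); their per-100 g macro fields remain authoritative for macro
bookkeeping. One published record (hot pepper) prints its serving energy in
the fat column; the fixture stores fat = 0.10 g/100 g, the only value
consistent with the printed 48.10 kcal.

Where the source publishes no glycemic-index or cholesterol value the
fixture stores 0 — a placeholder, not a measurement. Constraint tests
involving those foods exercise the mechanism, not the true GI of banku.

## Daily requirement

The basal metabolic rate is Mifflin-St Jeor:

    BMR = 10·W[kg] + 6.25·H[cm] − 5·age[y] + s,   s = +5 (male) / −161 (female)

The daily requirement is `Q = round(PAL · BMR)` (ties away from zero) with
PAL multipliers per WHO activity category:

| activity | PAL |
|---|---|
| extremely inactive / little-to-no exercise | 1.2 |
| sedentary | 1.375 |
| moderately active | 1.55 |
| vigorously active | 1.725 |
| extremely active | 1.9 |

These are the standard sedentary-to-athlete multipliers; the 1.2 anchor is
validated by the engine's reference user (round(1.2 · 1841.25) = 2210). Both
the PAL table and the macro split are keyword parameters of
`daily_requirement` for users who prefer other conventions.

Gram targets use a 50/20/30 calorie split: `C = 0.5·Q/4`, `P = 0.2·Q/4`,
`F = 0.3·Q/9`, rounded to 2 decimals. The split is chosen so the Atwater
closure `4C + 4P + 9F = Q` holds within 0.5 kcal; `DailyRequirement`
validates this at construction.

## Exercise expenditure

`E = coefficient · MET · W · minutes` with the engine's native coefficient
0.175 kcal·kg⁻¹·min⁻¹ per MET. This is 10× the textbook MET coefficient
(0.0175): the engine keeps its native scale for fidelity with the rest of
its budget arithmetic, and exposes `MET_COEFFICIENT_CONVENTIONAL = 0.0175`
as a documented switch (`exercise_energy(..., coefficient=...)`,
`new_day_ledger(..., met_coefficient=...)`) for users who want
physiologically conventional values.

## The deficit ledger

One ledger per calendar day (naive local midnight boundary). The calorie
deficit is a derived property, `d = Q + ΣE − ΣZ`, recomputed from the logged
entries, so the telescoping identity holds exactly by construction rather
than by maintained state. Macro deficits are requirement grams minus
consumed grams — meal macros are always grams actually consumed
(scaled by `N·f`), never raw per-100 g values, so they are dimensionally
comparable with the gram targets.

Overconsumption drives deficits negative; it is recorded and flagged, never
rejected. The predictor floors all budgets at zero. At the day boundary the
ledger resets to the full (possibly recomputed, e.g. after a weight update)
requirement; no residual carries over, because residual body energy cannot
be meaningfully quantified from diary data.

Whether exercise credit is counted cumulatively or per-interval is a
representational choice; the ledger telescopes all entries cumulatively,
which makes the two readings equivalent at day granularity.

## The genetic algorithm

A chromosome is a meal: one base component plus a variable-length tail of
up to `max_additional_components` (default 5) additional components, each
gene a (food, serving measure, serving count ≤ `max_servings` = 3) triple.

**Objective and fitness.** For available budget `D` (the floored calorie
deficit plus exercise credit) the objective is the slack `f = D − Z`,
minimised subject to: slack ≥ 0; consumed macros ≤ (C, P, F) componentwise;
every item's GI ≤ 55 when the user has any recorded diabetes level; total
cholesterol < 300 mg when cholesterol status is medium or high. Feasible
fitness is `1/(1 + f)` — strictly decreasing in slack, maximal (1.0) for a
meal that exactly fills the budget. Infeasible chromosomes receive
`1/(1 + |f| + 10⁴)` instead of being discarded, so early infeasible
populations can still evolve while any feasible chromosome strictly
dominates every infeasible one. Feasibility comparisons use a 1e-9
absolute tolerance.

**Operators.**
- *Selection:* tournament of size 3 (default), ties broken toward lower meal
  energy and then earlier index; fitness-proportional roulette is available
  via `selection_mode="roulette"`.
- *Crossover:* single-point whole-tail swap at the base/additional boundary
  with probability 0.65; the component multiset across the pair is conserved.
- *Mutation:* each component's three gene positions (food, serving measure,
  serving count) are independently marked with probability `mutation_prob`
  and re-drawn, plus one structural position per chromosome that inserts or
  removes a random tail component. Food replacement and the structural gene
  are what inject new genetic material: tail-swap crossover only recombines
  tails that already exist, and a finite population under full generational
  replacement loses diversity by drift, so without them the search fixates
  on the initial population's foods and tail lengths and large parts of the
  meal space become permanently unreachable (measured: oracle-match rates
  cap near 50% on exhaustively enumerable databases regardless of selection
  mode or run length).

**Loop.** Fully generational: each generation is replaced by exactly
`population_size` offspring. The best-ever feasible chromosome (and a
ranked archive of distinct feasible meals, used for top-k recommendations)
is kept outside the breeding population — elitism affects reporting only,
never breeding. Default configuration: population 30, crossover 0.65,
mutation 0.01, at most 500 generations, early stop after 50 generations
without improvement of the best feasible slack. A zero calorie budget
short-circuits to the no-solution marker. All randomness flows from a
single seeded generator, so runs are exactly reproducible.

The adopted defaults favour convergence speed on realistic databases. On
tiny exhaustively enumerable problems they find the true optimum in only
about half of runs; validating the machinery against the enumeration oracle
is therefore done with the exploration-heavy sweep setting
(mutation 0.5, stall 100), under which the GA matches the optimum slack
within 5% in ≥ 95 of 100 seeded runs and — as must hold under any
configuration — never reports a slack better than the oracle's.

`parameter_sweep` reports convergence as the generation of last improvement
rather than wall-clock time, which is hardware-dependent.

## Prediction flow

`build_state` extracts the floored budgets from the profile and the day's
ledger and activates the health constraints; `predict` runs the GA and
renders the result as per-item rows with group totals (serving label,
count, kcal, macro grams, 2 dp), residual deficits after the best meal, and
notes naming the active constraints. Diabetes activates the GI bound at any
recorded level (the conservative reading, since severity thresholds are not
part of the model); cholesterol activates at medium or high. An exhausted
budget or an infeasible search returns an empty recommendation with an
explanatory note — infeasibility is a result, not an error.

## Synthetic data

`generate_synthetic_db(n, seed)` emulates a staple-heavy West African
food-composition table: per-category macro ranges (carb-dominant staples
with high glycemic indices, protein/fat-dominant meats and fish carrying
the cholesterol, fat-heavy soups), GI ∈ [0, 110], cholesterol ∈
[0, 400] mg/100 g, and 1–3 household measures per food with weights in
[5, 400] g, all deterministic under the seed. It does **not** emulate
correlations within a real recipe corpus (co-occurrence of dishes, realistic
serving-size conventions, measured GI values), so passing tests on synthetic
databases demonstrate the arithmetic and search machinery, not
nutritional validity of recommendations on real foods.

## Problem sizes used in validation

- Oracle equivalence: 100 seeded runs on 6-food single-measure databases
  with ≤ 2 servings and ≤ 2 additional components (≈ 1100 enumerable meals
  per database) — small enough for exact enumeration, large enough that
  random guessing fails.
- Constraint soundness: 1000 randomized deficit states (with randomly
  activated GI/cholesterol limits) against the built-in fixture, with a
  reduced search configuration (population 20, ≤ 30 generations): the check
  asserts feasibility of whatever the search returns, which is independent
  of search effort.
- Convergence sweep: populations {20, 30, 40, 50, 70, 100} × mutation
  {0.001, 0.01, 0.08, 0.1, 0.5, 0.9}, capped at 120 generations.

## Known limitations

- The 0.175 MET coefficient yields expenditures 10× conventional values
  (e.g. 1561.9 kcal for a 30-minute moderate walk at 85 kg); use the
  conventional coefficient switch for physiological realism.
- GI and cholesterol placeholders (0) for composite fixture dishes make
  those foods unconditionally acceptable under health constraints.
- Custom serving weights that match no recorded measure fall back to the
  Atwater path, which yields 0 kcal for composite dishes known only per
  serving.
- The recommender is single-objective (slack); it does not balance macro
  fill quality, meal-type conventions (breakfast vs dinner), or user
  preference, and hypertension status is recorded but drives no constraint.
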