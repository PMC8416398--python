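# nutriga

Daily calorie and macronutrient bookkeeping with a genetic-algorithm meal
recommender, built for dietary decision support in obesity self-management.
It is aimed at nutrition-informatics developers, dieticians, and students of
dietetics who need a transparent, testable engine rather than a closed app:
every formula is a plain function, every data structure is serialisable, and
the whole pipeline runs from a food-composition CSV and a JSON-lines diary.

## The model

**Meal energy (Atwater accounting).** A meal is a list of components, each a
food with a household serving measure of weight *q* grams and a serving
count *N*. With per-100 g carbohydrate *c*, protein *p* and fat *h*, the meal
energy is

    Z = Σ_k  N_k · (q_k / 100) · (4 p_k + 4 c_k + 9 h_k)   [kcal]

Foods whose published records give per-serving figures that the macros do
not reproduce (composite dishes, juices) carry explicit per-serving records
that take precedence.

**Daily requirement.** The Mifflin-St Jeor basal metabolic rate
`BMR = 10W + 6.25H − 5·age + s` (s = +5 male, −161 female) is scaled by a
physical-activity-level multiplier (1.2 … 1.9 over the WHO activity
categories) to give the daily requirement *Q*, split 50/20/30
(carbohydrate/protein/fat by calories) into gram targets *C*, *P*, *F* so
that 4C + 4P + 9F ≈ Q.

**Energy balance.** Exercise adds `E = 0.175 · MET · W · minutes` and each
meal subtracts its energy, so the running calorie deficit is always
`d = Q + ΣE − ΣZ`; macro deficits are tracked in grams. Balances reset at
midnight — residual body energy is treated as unquantifiable and zeroed.

**Meal prediction.** Recommending the next meal is a constrained search: find
the meal whose energy best fills the available budget *D* without exceeding
it, while staying within the macro deficits, keeping every item's glycemic
index ≤ 55 for diabetic users, and total cholesterol < 300 mg for
high-cholesterol users. A genetic algorithm over meal chromosomes
(base dish + additional components) does the search, with fitness
`1/(1 + D − Z)` for feasible meals, tournament selection, tail-swap
crossover, and gene-replacement mutation (population 30, crossover 0.65,
mutation 0.01, up to 500 generations by default).

## Worked example

The package ships a built-in Ghanaian food fixture, so this runs with no
data download. A 24-year-old male, 177 cm / 85 kg, little-to-no exercise:

```
$ nutriga init-profile --age 24 --sex male --height-cm 177 --weight-kg 85 \
      --activity extremely_inactive --out profile.yaml
$ nutriga log-meal --profile profile.yaml --ledger diary.jsonl \
      --date 2021-08-27 --time 09:00 \
      --item "Waakye:Soup ladle:2"  --item "Salad:Stew ladle:2" \
      --item "Spaghetti:Stew ladle:2" --item "Gari:Table spoon:2" \
      --item "Fried fish:1 whole:1" --item "Tomato Stew:Stew ladle:1" \
      --item "Egg:1 egg:1" --item "Shito:Teaspoon:2"
$ nutriga report --profile profile.yaml --ledger diary.jsonl --date 2021-08-27
Daily report for 2021-08-27
  consumed 1017.14 kcal of 2210 kcal (+0.00 kcal exercise)
  remaining deficit: 1192.86 kcal
  carbohydrate: 153.00 g of 276.25 g
  protein: 60.00 g of 110.50 g
  fat: 33.00 g of 73.67 g
```

The requirement 2210 kcal is round(1.2 × 1841.25), where 1841.25 is the
Mifflin-St Jeor BMR for this user; the gram targets are the 50/20/30 split
(276.25 = 0.5·2210/4 etc.). The logged breakfast consumed 1017.14 kcal and
153 g carbohydrate, leaving a 1192.86 kcal budget. Asking for a
recommendation:

```
$ nutriga predict --profile profile.yaml --ledger diary.jsonl --date 2021-08-27 --seed 1
 group  meal_entry serving_size n_servings  calories_kcal  carbohydrate_g  protein_g  fat_g
     1       Banku   Small ball          1         334.96            23.8        2.4    0.4
     1 Apple juice       240 ml          2         278.40            29.0        0.0    0.0
     1 Wheat bread      1 slice          3         151.53            38.7        8.1    3.6
     1       Shito     Teaspoon          2          83.50             1.0        3.0    8.0
     1       Banku   Small ball          1         334.96            23.8        2.4    0.4
     1       Total                                1183.35           116.3       15.9   12.4

Residual after best meal: 9.51 kcal, 6.95 g carb, 34.60 g protein, 28.27 g fat
```

The recommended meal fills 1183.35 of the 1192.86 kcal budget (a slack of
9.51 kcal) and fits inside every macro deficit. With a diabetic profile the
same command only ever proposes items with glycemic index ≤ 55; with a
high-cholesterol profile, meals with ≥ 300 mg total cholesterol are
excluded.

The same operations are available as library calls (`daily_requirement`,
`log_meal`, `predict`, `evolve`, ...); see the module docstrings and
`docs/methods.md`.

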