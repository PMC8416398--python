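"""Food-composition database: I/O, built-in Ghanaian fixture, synthetic generator.

The on-disk schema is a single CSV (or a JSON mirror) with one row per food:

    id,name,category,carb_g_100g,protein_g_100g,fat_g_100g,
    glycemic_index,cholesterol_mg_100g,measures_json

``measures_json`` is a JSON-encoded list of household serving measures,
each ``{"label", "weight_g"}`` with an optional ``"per_serving"`` record
``{"energy_kcal", "carbohydrate_g", "protein_g", "fat_g"}`` for foods whose
source prints per-serving figures instead of (or inconsistently with) a
per-100 g decomposition.

The built-in fixture contains the Ghanaian dishes of the engine's worked
examples (kenkey, okro soup, waakye, banku, ...) with their published
composition values, so every test and demo runs without downloading the FAO
composition table or a food atlas.  Glycemic-index and cholesterol values
that the source does not print are stored as 0 placeholders.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .nutrition import (
    FoodItem,
    Meal,
    MealComponent,
    NutrientProfile,
    PerServingRecord,
    ServingMeasure,
)

__all__ = [
    "FoodDatabase",
    "load_food_db",
    "save_food_db",
    "builtin_fixture_db",
    "generate_synthetic_db",
    "crossover_example_parents",
    "sample_breakfast",
    "sample_recommended_meals",
]

CSV_COLUMNS = [
    "id",
    "name",
    "category",
    "carb_g_100g",
    "protein_g_100g",
    "fat_g_100g",
    "glycemic_index",
    "cholesterol_mg_100g",
    "measures_json",
]


class FoodDatabase:
    """An id-keyed collection of :class:`FoodItem` records."""

    def __init__(self, foods: Iterable[FoodItem]):
        self._foods: dict[str, FoodItem] = {}
        for food in foods:
            if food.id in self._foods:
                raise ValueError(f"duplicate food id {food.id!r}")
            self._foods[food.id] = food

    def __len__(self) -> int:
        return len(self._foods)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._foods.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    @property
    def foods(self) -> tuple[FoodItem, ...]:
        return tuple(self._foods.values())

    def get(self, food_id: str) -> FoodItem:
        try:
            return self._foods[food_id]
        except KeyError as exc:
            raise KeyError(f"no food with id {food_id!r}") from exc

    def find_by_name(self, name: str) -> FoodItem | None:
        """Case-insensitive lookup by display name or id."""
        lowered = name.lower()
        if lowered in self._foods:
            return self._foods[lowered]
        for food in self._foods.values():
            if food.name.lower() == lowered:
                return food
        return None


def _measure_to_dict(m: ServingMeasure) -> dict:
    out: dict = {"label": m.label, "weight_g": m.weight_g}
    if m.per_serving is not None:
        rec = {"energy_kcal": m.per_serving.energy_kcal}
        if m.per_serving.carbohydrate_g is not None:
            rec.update(
                carbohydrate_g=m.per_serving.carbohydrate_g,
                protein_g=m.per_serving.protein_g,
                fat_g=m.per_serving.fat_g,
            )
        out["per_serving"] = rec
    return out


def _food_to_row(food: FoodItem) -> dict:
    return {
        "id": food.id,
        "name": food.name,
        "category": food.category,
        "carb_g_100g": food.nutrients.carbohydrate_g_per_100g,
        "protein_g_100g": food.nutrients.protein_g_per_100g,
        "fat_g_100g": food.nutrients.fat_g_per_100g,
        "glycemic_index": food.nutrients.glycemic_index,
        "cholesterol_mg_100g": food.nutrients.cholesterol_mg_per_100g,
        "measures_json": json.dumps([_measure_to_dict(m) for m in food.measures]),
    }


def _food_from_row(row: dict, where: str) -> FoodItem:
    try:
        measures_raw = json.loads(row["measures_json"])
        measures = tuple(
            ServingMeasure(
                label=m["label"],
                weight_g=m["weight_g"],
                per_serving=(
                    PerServingRecord(**m["per_serving"]) if m.get("per_serving") else None
                ),
            )
            for m in measures_raw
        )
        return FoodItem(
            id=str(row["id"]),
            name=str(row["name"]),
            category=str(row["category"]),
            nutrients=NutrientProfile(
                carbohydrate_g_per_100g=row["carb_g_100g"],
                protein_g_per_100g=row["protein_g_100g"],
                fat_g_per_100g=row["fat_g_100g"],
                glycemic_index=row["glycemic_index"],
                cholesterol_mg_per_100g=row["cholesterol_mg_100g"],
            ),
            measures=measures,
        )
    except Exception as exc:
        raise ValueError(f"invalid food record at {where}: {exc}") from exc


def save_food_db(db: FoodDatabase, path: str | Path) -> None:
    """Write the database as CSV, or as the JSON mirror for ``.json`` paths."""
    path = Path(path)
    rows = [_food_to_row(f) for f in db]
    if path.suffix.lower() == ".json":
        foods = []
        for f in db:
            row = _food_to_row(f)
            row["measures"] = json.loads(row.pop("measures_json"))
            foods.append(row)
        path.write_text(json.dumps({"foods": foods}, indent=2) + "\n")
    else:
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def load_food_db(path: str | Path) -> FoodDatabase:
    """Load and validate a CSV or JSON food database.

    Raises ``ValueError`` naming the offending row for missing columns,
    negative values, malformed measures, or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        rows = []
        for i, food in enumerate(data.get("foods", [])):
            row = dict(food)
            row["measures_json"] = json.dumps(row.pop("measures", []))
            rows.append((f"{path}#foods[{i}]", row))
    else:
        frame = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        rows = [
            (f"{path}:row {i}", rec)
            for i, rec in enumerate(frame.to_dict(orient="records"))
        ]
    foods = [_food_from_row(row, where) for where, row in rows]
    return FoodDatabase(foods)


# ---------------------------------------------------------------------------
# Built-in fixture: the worked-example Ghanaian dishes
# ---------------------------------------------------------------------------

def _food(
    fid: str,
    name: str,
    category: str,
    carb: float,
    protein: float,
    fat: float,
    gi: float = 0.0,
    chol: float = 0.0,
    measures: tuple = (("100 g", 100.0, None),),
) -> FoodItem:
    return FoodItem(
        id=fid,
        name=name,
        category=category,
        nutrients=NutrientProfile(
            carbohydrate_g_per_100g=carb,
            protein_g_per_100g=protein,
            fat_g_per_100g=fat,
            glycemic_index=gi,
            cholesterol_mg_per_100g=chol,
        ),
        measures=tuple(
            ServingMeasure(
                label=label,
                weight_g=weight,
                per_serving=PerServingRecord(**rec) if rec else None,
            )
            for label, weight, rec in measures
        ),
    )


def builtin_fixture_db() -> FoodDatabase:
    """The built-in worked-example database.

    Foods with an Atwater-consistent per-100 g decomposition carry only the
    composition record.  Foods whose source prints a per-serving calorie
    figure that the macros do not reproduce (rice ball, rabbit, smoked tuna)
    keep their per-100 g macros and carry the printed energy as a per-serving
    record.  Composite dishes known only by their per-serving figures
    (waakye, banku, ...) carry full per-serving records; their per-100 g
    fields are zero placeholders, as are unpublished glycemic-index and
    cholesterol values.  Hot pepper's fat is stored as 0.10 g/100 g, the only
    value consistent with its published 48.10 kcal serving energy.
    """
    foods = [
        # Atwater-consistent per-100 g records
        _food("kenkey", "Kenkey (Ga)", "staple", 25.00, 3.50, 0.60, gi=35.0,
              measures=(("standard ball", 285.94, None),)),
        _food("okro-soup", "Okro soup", "soup", 4.20, 1.90, 2.80, gi=30.0,
              measures=(("soup ladle", 100.0, None),)),
        _food("hot-pepper", "Hot pepper", "spice", 10.70, 1.10, 0.10,
              measures=(("100 g", 100.0, None),)),
        _food("tilapia", "Tilapia", "fish", 0.00, 18.80, 2.70,
              measures=(("100 g", 100.0, None),)),
        _food("palm-nut-soup", "Palm nut soup", "soup", 16.20, 1.80, 46.80, gi=20.0,
              measures=(("soup ladle", 100.0, None),)),
        _food("okro-stew", "Okro stew", "stew", 5.00, 2.80, 11.60,
              measures=(("100 g", 100.0, None),)),
        _food("lamb", "Lamb/mutton", "meat", 0.00, 16.50, 21.20,
              measures=(("100 g", 100.0, None),)),
        # per-100 g macros with published per-serving energies (not Atwater-
        # reproducible; the printed figure wins for energy)
        _food("rice-ball", "Rice ball", "staple", 79.60, 7.20, 0.40, gi=70.0,
              measures=(("standard ball", 222.39, {"energy_kcal": 2340.43}),)),
        _food("rabbit", "Rabbit", "meat", 0.00, 21.60, 21.10,
              measures=(("100 g", 100.0, {"energy_kcal": 129.60}),)),
        _food("smoked-tuna", "Smoked tuna", "fish", 0.00, 31.80, 31.70, gi=90.0,
              measures=(("100 g", 100.0, {"energy_kcal": 129.90}),)),
        # composite dishes known only per serving (per-100 g zeros are
        # placeholders; serving weights for unpublished measures are nominal)
        _food("waakye", "Waakye", "staple", 0, 0, 0,
              measures=(("Soup ladle", 150.0,
                         {"energy_kcal": 225.00, "carbohydrate_g": 54.0,
                          "protein_g": 8.0, "fat_g": 6.0}),)),
        _food("salad", "Salad", "vegetable", 0, 0, 0,
              measures=(("Stew ladle", 100.0,
                         {"energy_kcal": 7.50, "carbohydrate_g": 1.5,
                          "protein_g": 0.5, "fat_g": 0.0}),)),
        _food("spaghetti", "Spaghetti", "staple", 0, 0, 0,
              measures=(("Stew ladle", 100.0,
                         {"energy_kcal": 67.00, "carbohydrate_g": 14.0,
                          "protein_g": 3.0, "fat_g": 0.5}),)),
        _food("gari", "Gari", "staple", 0, 0, 0,
              measures=(("Table spoon", 20.0,
                         {"energy_kcal": 27.52, "carbohydrate_g": 6.5,
                          "protein_g": 0.0, "fat_g": 0.0}),)),
        _food("fried-fish", "Fried fish", "fish", 0, 0, 0,
              measures=(("1 whole", 120.0,
                         {"energy_kcal": 78.00, "carbohydrate_g": 0.0,
                          "protein_g": 15.0, "fat_g": 2.0}),)),
        _food("tomato-stew", "Tomato Stew", "stew", 0, 0, 0,
              measures=(("Stew ladle", 100.0,
                         {"energy_kcal": 114.60, "carbohydrate_g": 0.0,
                          "protein_g": 13.0, "fat_g": 2.0}),)),
        _food("egg", "Egg", "egg", 0, 0, 0,
              measures=(("1 egg", 50.0,
                         {"energy_kcal": 87.00, "carbohydrate_g": 0.0,
                          "protein_g": 6.0, "fat_g": 8.0}),)),
        _food("shito", "Shito", "spice", 0, 0, 0,
              measures=(("Teaspoon", 10.0,
                         {"energy_kcal": 41.75, "carbohydrate_g": 0.5,
                          "protein_g": 1.5, "fat_g": 4.0}),)),
        _food("banku", "Banku", "staple", 0, 0, 0,
              measures=(("Small ball", 200.0,
                         {"energy_kcal": 334.96, "carbohydrate_g": 23.8,
                          "protein_g": 2.4, "fat_g": 0.4}),)),
        _food("apple-juice", "Apple juice", "drink", 0, 0, 0,
              measures=(("240 ml", 240.0,
                         {"energy_kcal": 139.20, "carbohydrate_g": 14.5,
                          "protein_g": 0.0, "fat_g": 0.0}),)),
        _food("wheat-bread", "Wheat bread", "staple", 0, 0, 0,
              measures=(("1 slice", 30.0,
                         {"energy_kcal": 50.51, "carbohydrate_g": 12.9,
                          "protein_g": 2.7, "fat_g": 1.2}),)),
    ]
    return FoodDatabase(foods)


# ---------------------------------------------------------------------------
# Worked-example meals built from the fixture
# ---------------------------------------------------------------------------

def _component(db: FoodDatabase, food_id: str, n: int = 1) -> MealComponent:
    food = db.get(food_id)
    measure = food.measures[0]
    return MealComponent(
        food=food,
        serving_weight_g=measure.weight_g,
        n_servings=n,
        measure_label=measure.label,
    )


def crossover_example_parents(db: FoodDatabase) -> tuple[Meal, Meal]:
    """The two parent chromosome meals of the crossover worked example.

    Parent 1 is a kenkey-based meal (okro soup, hot pepper, tilapia tail);
    parent 2 is a rice-ball-based meal (palm nut soup x2, rabbit, smoked
    tuna x2 tail).
    """
    x1 = Meal(components=(
        _component(db, "kenkey"),
        _component(db, "okro-soup"),
        _component(db, "hot-pepper"),
        _component(db, "tilapia"),
    ))
    x2 = Meal(components=(
        _component(db, "rice-ball"),
        _component(db, "palm-nut-soup", n=2),
        _component(db, "rabbit"),
        _component(db, "smoked-tuna", n=2),
    ))
    return x1, x2


def sample_breakfast(db: FoodDatabase) -> Meal:
    """The worked-example logged breakfast (waakye, salad, spaghetti, ...)."""
    return Meal(components=(
        _component(db, "waakye", n=2),
        _component(db, "salad", n=2),
        _component(db, "spaghetti", n=2),
        _component(db, "gari", n=2),
        _component(db, "fried-fish"),
        _component(db, "tomato-stew"),
        _component(db, "egg"),
        _component(db, "shito", n=2),
    ))


def sample_recommended_meals(db: FoodDatabase) -> tuple[Meal, Meal]:
    """The worked-example recommendation: a main course and a drinks group."""
    main = Meal(components=(
        _component(db, "banku"),
        _component(db, "okro-stew"),
        _component(db, "tilapia"),
        _component(db, "lamb"),
    ))
    drinks = Meal(components=(
        _component(db, "apple-juice", n=2),
        _component(db, "wheat-bread"),
    ))
    return main, drinks


# ---------------------------------------------------------------------------
# Synthetic database generator
# ---------------------------------------------------------------------------

#: Per-category (carb, protein, fat) ranges in g/100 g, GI range, cholesterol
#: range in mg/100 g.  Ranges mimic staple-heavy West African food tables:
#: starchy staples are carb-dominant with higher glycemic indices, meats and
#: fish are protein/fat-dominant and carry the cholesterol.
_CATEGORY_RANGES = {
    "staple": ((15, 80), (1, 10), (0, 5), (40, 110), (0, 0)),
    "vegetable": ((2, 12), (1, 4), (0, 2), (0, 40), (0, 0)),
    "legume": ((15, 45), (5, 25), (1, 15), (20, 55), (0, 0)),
    "fruit": ((5, 25), (0, 2), (0, 1), (25, 75), (0, 0)),
    "fish": ((0, 2), (15, 32), (1, 20), (0, 10), (40, 120)),
    "meat": ((0, 2), (15, 30), (5, 40), (0, 10), (50, 400)),
    "soup": ((2, 18), (1, 8), (2, 48), (10, 45), (0, 60)),
    "spice": ((5, 15), (1, 5), (0, 12), (0, 20), (0, 0)),
    "drink": ((5, 30), (0, 3), (0, 2), (30, 90), (0, 0)),
}

_MEASURE_LABELS = [
    "soup ladle", "stew ladle", "teaspoon", "table spoon", "small ball",
    "standard ball", "portion", "slice", "cup", "piece",
]


def generate_synthetic_db(n: int, seed: int) -> FoodDatabase:
    """Generate ``n`` synthetic foods with category-conditioned compositions.

    Deterministic under ``seed``.  Each food gets 1–3 serving measures with
    weights in [5, 400] g; glycemic index stays in [0, 110] and cholesterol
    in [0, 400] mg/100 g by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    categories = list(_CATEGORY_RANGES)
    foods = []
    for i in range(n):
        category = categories[int(rng.integers(len(categories)))]
        (c_lo, c_hi), (p_lo, p_hi), (f_lo, f_hi), (g_lo, g_hi), (ch_lo, ch_hi) = (
            _CATEGORY_RANGES[category]
        )
        n_measures = int(rng.integers(1, 4))
        labels = rng.choice(_MEASURE_LABELS, size=n_measures, replace=False)
        measures = tuple(
            ServingMeasure(label=str(label), weight_g=float(np.round(rng.uniform(5, 400), 1)))
            for label in labels
        )
        foods.append(
            FoodItem(
                id=f"syn-{i:04d}",
                name=f"Synthetic {category} {i}",
                category=category,
                nutrients=NutrientProfile(
                    carbohydrate_g_per_100g=float(np.round(rng.uniform(c_lo, c_hi), 2)),
                    protein_g_per_100g=float(np.round(rng.uniform(p_lo, p_hi), 2)),
                    fat_g_per_100g=float(np.round(rng.uniform(f_lo, f_hi), 2)),
                    glycemic_index=float(np.round(rng.uniform(g_lo, g_hi), 1)),
                    cholesterol_mg_per_100g=float(np.round(rng.uniform(ch_lo, ch_hi), 1)),
                ),
                measures=measures,
            )
        )
    return FoodDatabase(foods)
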