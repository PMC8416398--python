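"""Shared fixtures and the brute-force enumeration oracle."""

import itertools

import numpy as np
import pytest

import nutriga as ng
from nutriga.nutrition import (
    FoodItem,
    Meal,
    MealComponent,
    NutrientProfile,
    ServingMeasure,
)


@pytest.fixture(scope="session")
def fixture_db():
    return ng.builtin_fixture_db()


@pytest.fixture
def sample_profile():
    """The worked-example user: 24 y male, 177 cm, 85 kg, little-to-no exercise."""
    return ng.UserProfile(
        age_years=24,
        sex=ng.Sex.male,
        height_cm=177.0,
        weight_kg=85.0,
        activity_level=ng.ActivityLevel.extremely_inactive,
    )


def tiny_single_measure_db(n_foods: int, seed: int) -> ng.FoodDatabase:
    """A small one-measure-per-food database for exhaustive-search tests."""
    rng = np.random.default_rng(seed)
    foods = []
    for i in range(n_foods):
        foods.append(
            FoodItem(
                id=f"f{i}",
                name=f"food {i}",
                category="other",
                nutrients=NutrientProfile(
                    carbohydrate_g_per_100g=float(rng.uniform(0, 60)),
                    protein_g_per_100g=float(rng.uniform(0, 30)),
                    fat_g_per_100g=float(rng.uniform(0, 30)),
                ),
                measures=(
                    ServingMeasure(label="portion", weight_g=float(rng.uniform(30, 300))),
                ),
            )
        )
    return ng.FoodDatabase(foods)


def enumerate_meals(db: ng.FoodDatabase, max_servings: int, max_additional: int):
    """Every meal expressible as base + tail multiset over the database."""
    options = [
        MealComponent(
            food=food, serving_weight_g=m.weight_g, n_servings=n, measure_label=m.label
        )
        for food in db
        for m in food.measures
        for n in range(1, max_servings + 1)
    ]
    for base in options:
        for k in range(max_additional + 1):
            for tail in itertools.combinations_with_replacement(options, k):
                yield Meal(components=(base,) + tail)


def oracle_best(db, state, max_servings: int, max_additional: int):
    """Exhaustive-search optimum: the feasible meal with the smallest slack."""
    best = None
    for meal in enumerate_meals(db, max_servings, max_additional):
        ec = ng.evaluate(meal, state)
        if ec.feasible and (best is None or ec.objective < best.objective):
            best = ec
    return best
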