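"""Food data model and Atwater-factor energy arithmetic.

Meals are represented as ordered lists of components, each tying a food's
per-100 g composition record to a chosen household serving measure (a "food
atlas" weight ``q`` in grams) and a serving count ``N``.  Energy is computed
with the general Atwater factors — 4 kcal/g for protein and carbohydrate,
9 kcal/g for fat — scaled by the dimensionless serving factor ``f = q/100``:

    energy = N * (q / 100) * (4*protein + 4*carbohydrate + 9*fat)

Some composition sources print a per-serving calorie figure that is not
reproducible from the macro columns (restaurant-style composite dishes, juices
with non-macro energy accounting, rounding in the source table).  Such foods
carry an explicit :class:`PerServingRecord` on the serving measure; when
present it takes precedence over the Atwater computation for that measure.

Macronutrient totals are always reported in grams actually consumed, i.e.
scaled by ``N * f``, so they are directly comparable with gram-denominated
daily requirements.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ATWATER_CARB",
    "ATWATER_PROTEIN",
    "ATWATER_FAT",
    "GLYCEMIC_INDEX_MAX",
    "LOW_GI_LIMIT",
    "NutrientProfile",
    "PerServingRecord",
    "ServingMeasure",
    "FoodItem",
    "MealComponent",
    "Meal",
    "MacroTotals",
    "scale_factor",
    "component_energy",
    "component_macros",
    "component_cholesterol",
    "meal_energy",
    "meal_macros",
    "meal_cholesterol",
    "gi_within_limit",
]

#: General Atwater energy-conversion factors, kcal per gram.
ATWATER_CARB = 4.0
ATWATER_PROTEIN = 4.0
ATWATER_FAT = 9.0

#: Upper end of the glycemic-index scale (glucose = 100; a few foods exceed it).
GLYCEMIC_INDEX_MAX = 110.0

#: Conventional "low GI" cut-off used for diabetic meal constraints.
LOW_GI_LIMIT = 55.0


class NutrientProfile(BaseModel):
    """Per-100 g nutrient composition of a food."""

    model_config = ConfigDict(frozen=True)

    carbohydrate_g_per_100g: float = Field(ge=0)
    protein_g_per_100g: float = Field(ge=0)
    fat_g_per_100g: float = Field(ge=0)
    glycemic_index: float = Field(default=0.0, ge=0, le=GLYCEMIC_INDEX_MAX)
    cholesterol_mg_per_100g: float = Field(default=0.0, ge=0)


class PerServingRecord(BaseModel):
    """Printed per-serving energy (and optionally macros) for one measure.

    ``energy_kcal`` always overrides the Atwater computation for the measure
    it is attached to.  Macro fields, when present, override the scaled
    per-100 g values; when ``None`` the macros still come from the food's
    :class:`NutrientProfile`.
    """

    model_config = ConfigDict(frozen=True)

    energy_kcal: float = Field(ge=0)
    carbohydrate_g: Optional[float] = Field(default=None, ge=0)
    protein_g: Optional[float] = Field(default=None, ge=0)
    fat_g: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _macros_all_or_none(self) -> "PerServingRecord":
        macros = (self.carbohydrate_g, self.protein_g, self.fat_g)
        if any(m is not None for m in macros) and any(m is None for m in macros):
            raise ValueError("per-serving macros must be given together or not at all")
        return self


class ServingMeasure(BaseModel):
    """A named household serving (ladle, teaspoon, slice, ...) with its gram weight."""

    model_config = ConfigDict(frozen=True)

    label: str
    weight_g: float = Field(gt=0)
    per_serving: Optional[PerServingRecord] = None


class FoodItem(BaseModel):
    """A food-database entry: identity, per-100 g composition, serving measures."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    category: str = "other"
    nutrients: NutrientProfile
    measures: tuple[ServingMeasure, ...] = Field(min_length=1)

    def find_measure(
        self, label: str | None = None, weight_g: float | None = None
    ) -> Optional[ServingMeasure]:
        """Locate a serving measure by label (case-insensitive) or gram weight."""
        if label is not None:
            for m in self.measures:
                if m.label.lower() == label.lower():
                    return m
        if weight_g is not None:
            for m in self.measures:
                if abs(m.weight_g - weight_g) <= 1e-9:
                    return m
        return None


class MealComponent(BaseModel):
    """One food in a meal: the chosen serving weight ``q`` and count ``N``."""

    model_config = ConfigDict(frozen=True)

    food: FoodItem
    serving_weight_g: float = Field(gt=0)
    n_servings: int = Field(ge=1)
    measure_label: Optional[str] = None


class Meal(BaseModel):
    """An ordered list of meal components.

    The first component is the base dish; any remainder are additional
    components (the tail exchanged by the genetic operators).  An empty
    component list is permitted at this layer so that reporting code can
    represent "nothing eaten"; candidate meals produced by the optimiser
    always have at least one component.
    """

    model_config = ConfigDict(frozen=True)

    components: tuple[MealComponent, ...] = ()

    @property
    def base(self) -> MealComponent:
        return self.components[0]

    @property
    def tail(self) -> tuple[MealComponent, ...]:
        return self.components[1:]


class MacroTotals(NamedTuple):
    """Grams of each macronutrient actually consumed."""

    carbohydrate_g: float
    protein_g: float
    fat_g: float

    def __add__(self, other):  # type: ignore[override]
        return MacroTotals(
            self.carbohydrate_g + other.carbohydrate_g,
            self.protein_g + other.protein_g,
            self.fat_g + other.fat_g,
        )


def scale_factor(serving_weight_g: float) -> float:
    """Dimensionless serving scale ``f = q / 100`` for a gram weight ``q``."""
    if serving_weight_g < 0:
        raise ValueError(f"serving weight must be nonnegative, got {serving_weight_g}")
    return serving_weight_g / 100.0


def _resolved_record(component: MealComponent) -> Optional[PerServingRecord]:
    measure = component.food.find_measure(
        label=component.measure_label, weight_g=component.serving_weight_g
    )
    return measure.per_serving if measure is not None else None


def component_energy(component: MealComponent) -> float:
    """Energy of one meal component in kcal.

    Uses the printed per-serving record when the component's measure carries
    one, otherwise the Atwater formula ``N * f * (4p + 4c + 9h)`` on the
    per-100 g composition.
    """
    record = _resolved_record(component)
    if record is not None:
        return component.n_servings * record.energy_kcal
    nut = component.food.nutrients
    per_100g = (
        ATWATER_PROTEIN * nut.protein_g_per_100g
        + ATWATER_CARB * nut.carbohydrate_g_per_100g
        + ATWATER_FAT * nut.fat_g_per_100g
    )
    return component.n_servings * scale_factor(component.serving_weight_g) * per_100g


def component_macros(component: MealComponent) -> MacroTotals:
    """Macronutrient grams consumed for one component (scaled by ``N * f``)."""
    record = _resolved_record(component)
    if record is not None and record.carbohydrate_g is not None:
        n = component.n_servings
        return MacroTotals(
            n * record.carbohydrate_g,
            n * record.protein_g,  # type: ignore[operator]
            n * record.fat_g,  # type: ignore[operator]
        )
    nut = component.food.nutrients
    scale = component.n_servings * scale_factor(component.serving_weight_g)
    return MacroTotals(
        scale * nut.carbohydrate_g_per_100g,
        scale * nut.protein_g_per_100g,
        scale * nut.fat_g_per_100g,
    )


def component_cholesterol(component: MealComponent) -> float:
    """Cholesterol consumed for one component, mg (always per-100 g scaled)."""
    scale = component.n_servings * scale_factor(component.serving_weight_g)
    return scale * component.food.nutrients.cholesterol_mg_per_100g


def meal_energy(meal: Meal) -> float:
    """Total meal energy in kcal: sum of component energies."""
    return sum(component_energy(c) for c in meal.components)


def meal_macros(meal: Meal) -> MacroTotals:
    """Total grams of carbohydrate, protein and fat consumed in a meal."""
    totals = MacroTotals(0.0, 0.0, 0.0)
    for c in meal.components:
        totals = totals + component_macros(c)
    return totals


def meal_cholesterol(meal: Meal) -> float:
    """Total cholesterol in a meal, mg."""
    return sum(component_cholesterol(c) for c in meal.components)


def gi_within_limit(meal: Meal, limit: float) -> bool:
    """True iff every component's glycemic index lies in ``[0, limit]``.

    The bound is enforced per item: one high-GI food makes the whole meal
    unsuitable for a glycemic-restricted diet regardless of the other items.
    """
    if limit < 0:
        raise ValueError("glycemic-index limit must be nonnegative")
    return all(c.food.nutrients.glycemic_index <= limit for c in meal.components)
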