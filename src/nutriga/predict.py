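"""Meal prediction: deficit state assembly, GA invocation, and reporting.

The prediction flow extracts the user's remaining calorie and macro budgets
from the day's ledger, activates health constraints from the profile
(a per-item glycemic-index bound of 55 for any recorded diabetes level, a
300 mg meal-cholesterol bound for medium-or-worse cholesterol status), runs
the evolutionary search, and renders the winning meal(s) as a per-item
table with group totals and residual deficits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .budget import DayLedger, HealthLevel, UserProfile
from .food_db import FoodDatabase
from .ga import DeficitState, EvaluatedChromosome, GAConfig, evolve
from .nutrition import (
    LOW_GI_LIMIT,
    MacroTotals,
    Meal,
    component_energy,
    component_macros,
    meal_macros,
)

__all__ = [
    "CHOLESTEROL_LIMIT_MG",
    "Recommendation",
    "build_state",
    "predict",
    "recommendation_frame",
    "render_text",
]

#: WHO-style daily cholesterol bound applied to recommended meals, mg.
CHOLESTEROL_LIMIT_MG = 300.0

_FRAME_COLUMNS = [
    "group",
    "meal_entry",
    "serving_size",
    "n_servings",
    "calories_kcal",
    "carbohydrate_g",
    "protein_g",
    "fat_g",
]


@dataclass
class Recommendation:
    """One or more recommended meals plus the budgets they leave behind."""

    meals: list[Meal]
    residual_kcal: float
    residual_macros: MacroTotals
    notes: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.meals


def build_state(profile: UserProfile, ledger: DayLedger) -> DeficitState:
    """Assemble the GA's deficit state from the profile and today's ledger.

    Budgets are floored at zero: an overconsumed day leaves nothing to
    recommend into.  Health constraints activate from the profile's recorded
    levels.
    """
    macros = ledger.macro_deficits
    return DeficitState(
        available_kcal=max(0.0, ledger.calorie_deficit),
        carb_deficit_g=max(0.0, macros.carbohydrate_g),
        protein_deficit_g=max(0.0, macros.protein_g),
        fat_deficit_g=max(0.0, macros.fat_g),
        gi_limit=LOW_GI_LIMIT if profile.diabetes != HealthLevel.none else None,
        cholesterol_limit_mg=(
            CHOLESTEROL_LIMIT_MG
            if profile.cholesterol in (HealthLevel.medium, HealthLevel.high)
            else None
        ),
    )


def _constraint_notes(state: DeficitState) -> list[str]:
    notes = []
    if state.gi_limit is not None:
        notes.append(f"low-GI constraint active: every item GI <= {state.gi_limit:g}")
    if state.cholesterol_limit_mg is not None:
        notes.append(
            f"cholesterol constraint active: meal total < {state.cholesterol_limit_mg:g} mg"
        )
    return notes


def predict(
    profile: UserProfile,
    ledger: DayLedger,
    db: FoodDatabase,
    config: GAConfig | None = None,
    top_k: int = 1,
) -> Recommendation:
    """Recommend up to ``top_k`` distinct feasible meals for the day's budgets.

    Returns an empty recommendation with an explanatory note when the budget
    is exhausted or no feasible meal exists.
    """
    state = build_state(profile, ledger)
    notes = _constraint_notes(state)
    if state.available_kcal <= 0:
        return Recommendation(
            meals=[],
            residual_kcal=state.available_kcal,
            residual_macros=MacroTotals(
                state.carb_deficit_g, state.protein_deficit_g, state.fat_deficit_g
            ),
            notes=notes + ["no remaining calorie budget for today"],
        )
    result = evolve(db, state, config or GAConfig())
    if result.best is None:
        return Recommendation(
            meals=[],
            residual_kcal=state.available_kcal,
            residual_macros=MacroTotals(
                state.carb_deficit_g, state.protein_deficit_g, state.fat_deficit_g
            ),
            notes=notes + ["no feasible meal found under the active constraints"],
        )
    chosen: list[EvaluatedChromosome] = result.top(max(1, top_k))
    meals = [c.meal for c in chosen]
    # residuals assume the single best meal is consumed
    best = chosen[0]
    eaten = meal_macros(best.meal)
    residual = MacroTotals(
        state.carb_deficit_g - eaten.carbohydrate_g,
        state.protein_deficit_g - eaten.protein_g,
        state.fat_deficit_g - eaten.fat_g,
    )
    return Recommendation(
        meals=meals,
        residual_kcal=state.available_kcal - best.energy_kcal,
        residual_macros=residual,
        notes=notes,
    )


def recommendation_frame(rec: Recommendation) -> pd.DataFrame:
    """Tabulate a recommendation: one row per item plus a total row per group."""
    rows = []
    for g, meal in enumerate(rec.meals, start=1):
        group_energy = 0.0
        group_macros = MacroTotals(0.0, 0.0, 0.0)
        for c in meal.components:
            energy = component_energy(c)
            macros = component_macros(c)
            group_energy += energy
            group_macros = group_macros + macros
            rows.append(
                {
                    "group": g,
                    "meal_entry": c.food.name,
                    "serving_size": c.measure_label or f"{c.serving_weight_g:g} g",
                    "n_servings": c.n_servings,
                    "calories_kcal": round(energy, 2),
                    "carbohydrate_g": round(macros.carbohydrate_g, 2),
                    "protein_g": round(macros.protein_g, 2),
                    "fat_g": round(macros.fat_g, 2),
                }
            )
        rows.append(
            {
                "group": g,
                "meal_entry": "Total",
                "serving_size": "",
                "n_servings": "",
                "calories_kcal": round(group_energy, 2),
                "carbohydrate_g": round(group_macros.carbohydrate_g, 2),
                "protein_g": round(group_macros.protein_g, 2),
                "fat_g": round(group_macros.fat_g, 2),
            }
        )
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def render_text(rec: Recommendation) -> str:
    """Aligned plain-text rendering of a recommendation."""
    lines = []
    if rec.empty:
        lines.append("No meal recommendation.")
    else:
        frame = recommendation_frame(rec)
        lines.append(frame.to_string(index=False))
        lines.append("")
        lines.append(
            "Residual after best meal: "
            f"{rec.residual_kcal:.2f} kcal, "
            f"{rec.residual_macros.carbohydrate_g:.2f} g carb, "
            f"{rec.residual_macros.protein_g:.2f} g protein, "
            f"{rec.residual_macros.fat_g:.2f} g fat"
        )
    for note in rec.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines)
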