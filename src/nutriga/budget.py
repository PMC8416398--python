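"""Daily energy requirements, exercise expenditure, and the deficit ledger.

The daily calorie requirement Q is the Mifflin-St Jeor basal metabolic rate

    BMR = 10*W + 6.25*H - 5*age + s      (s = +5 male, -161 female)

multiplied by a physical-activity-level (PAL) factor keyed to the WHO
activity categories, rounded to the nearest kcal.  Q is split into gram
targets with a 50/20/30 carbohydrate/protein/fat calorie split using the
Atwater factors, so 4C + 4P + 9F recovers Q to within rounding.

Exercise expenditure uses the MET formula E = coeff * MET * W * minutes with
the engine's native coefficient 0.175; the conventional coefficient
0.0175 kcal.kg^-1.min^-1 is exposed as `MET_COEFFICIENT_CONVENTIONAL` for
users who want textbook-scaled values.

A `DayLedger` is the per-calendar-day diary.  The calorie deficit is always
the telescoped balance  d = Q + sum(E*) - sum(Z);  it is recomputed from the
logged entries rather than stored, so the telescoping identity holds by
construction.  At the day boundary all residual balance is discarded and a
fresh ledger starts from the (possibly recomputed) requirement — residual
body energy is treated as unquantifiable and zeroed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .nutrition import MacroTotals, Meal, MealComponent, meal_energy, meal_macros

if TYPE_CHECKING:  # pragma: no cover
    from .food_db import FoodDatabase

__all__ = [
    "Sex",
    "ActivityLevel",
    "HealthLevel",
    "UserProfile",
    "DailyRequirement",
    "ExerciseEntry",
    "MealEntry",
    "DayLedger",
    "DEFAULT_PAL",
    "DEFAULT_MACRO_SPLIT",
    "MET_COEFFICIENT",
    "MET_COEFFICIENT_CONVENTIONAL",
    "round_half_up",
    "bmr",
    "daily_requirement",
    "exercise_energy",
    "new_day_ledger",
    "log_meal",
    "log_exercise",
    "end_of_day_reset",
    "save_profile",
    "load_profile",
    "save_ledger",
    "load_ledger",
]


class Sex(str, Enum):
    male = "male"
    female = "female"


#: Mifflin-St Jeor sex offset, kcal/day.
SEX_OFFSET = {Sex.male: 5.0, Sex.female: -161.0}


class ActivityLevel(str, Enum):
    """WHO physical-activity categories."""

    extremely_inactive = "extremely_inactive"
    sedentary = "sedentary"
    moderately_active = "moderately_active"
    vigorously_active = "vigorously_active"
    extremely_active = "extremely_active"


#: PAL multipliers per activity category (BMR -> total daily requirement).
DEFAULT_PAL: Mapping[ActivityLevel, float] = {
    ActivityLevel.extremely_inactive: 1.2,
    ActivityLevel.sedentary: 1.375,
    ActivityLevel.moderately_active: 1.55,
    ActivityLevel.vigorously_active: 1.725,
    ActivityLevel.extremely_active: 1.9,
}

#: Fraction of daily calories from carbohydrate, protein, fat.
DEFAULT_MACRO_SPLIT = (0.50, 0.20, 0.30)

#: Native MET-formula coefficient (kcal per MET.kg.min).
MET_COEFFICIENT = 0.175
#: Conventional textbook coefficient; pass as ``coefficient=`` to rescale.
MET_COEFFICIENT_CONVENTIONAL = 0.0175


class HealthLevel(str, Enum):
    none = "none"
    low = "low"
    medium = "medium"
    high = "high"


class UserProfile(BaseModel):
    """Anthropometrics, activity level, and health flags for one user.

    ``hypertension`` and similar extra flags are recorded for completeness but
    drive no recommendation constraint.
    """

    model_config = ConfigDict(frozen=True)

    age_years: float = Field(gt=0)
    sex: Sex
    height_cm: float = Field(gt=0)
    weight_kg: float = Field(gt=0)
    activity_level: ActivityLevel = ActivityLevel.extremely_inactive
    diabetes: HealthLevel = HealthLevel.none
    cholesterol: HealthLevel = HealthLevel.none
    hypertension: HealthLevel = HealthLevel.none


class DailyRequirement(BaseModel):
    """Daily calorie requirement Q and its gram-denominated macro targets."""

    model_config = ConfigDict(frozen=True)

    calories_kcal: float = Field(gt=0)
    carbohydrate_g: float = Field(gt=0)
    protein_g: float = Field(gt=0)
    fat_g: float = Field(gt=0)

    @model_validator(mode="after")
    def _atwater_closure(self) -> "DailyRequirement":
        recon = 4 * self.carbohydrate_g + 4 * self.protein_g + 9 * self.fat_g
        if abs(recon - self.calories_kcal) > 0.5:
            raise ValueError(
                f"macro targets reconstruct {recon:.2f} kcal, "
                f"not {self.calories_kcal:.2f} (Atwater closure violated)"
            )
        return self

    @property
    def macros(self) -> MacroTotals:
        return MacroTotals(self.carbohydrate_g, self.protein_g, self.fat_g)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (ledger reporting convention)."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def bmr(profile: UserProfile) -> float:
    """Mifflin-St Jeor basal metabolic rate, kcal/day."""
    return (
        10.0 * profile.weight_kg
        + 6.25 * profile.height_cm
        - 5.0 * profile.age_years
        + SEX_OFFSET[profile.sex]
    )


def daily_requirement(
    profile: UserProfile,
    pal: Mapping[ActivityLevel, float] | None = None,
    macro_split: tuple[float, float, float] = DEFAULT_MACRO_SPLIT,
) -> DailyRequirement:
    """Daily requirement Q = round(PAL * BMR) with 50/20/30 macro targets.

    Gram targets are C = carb_frac*Q/4, P = prot_frac*Q/4, F = fat_frac*Q/9,
    rounded to 2 decimals.
    """
    pal = DEFAULT_PAL if pal is None else pal
    try:
        multiplier = pal[profile.activity_level]
    except KeyError as exc:
        raise ValueError(f"no PAL multiplier for activity level {profile.activity_level!r}") from exc
    carb_frac, prot_frac, fat_frac = macro_split
    q = round_half_up(multiplier * bmr(profile))
    return DailyRequirement(
        calories_kcal=q,
        carbohydrate_g=round_half_up(carb_frac * q / 4.0, 2),
        protein_g=round_half_up(prot_frac * q / 4.0, 2),
        fat_g=round_half_up(fat_frac * q / 9.0, 2),
    )


def exercise_energy(
    met: float,
    weight_kg: float,
    duration_min: float,
    coefficient: float = MET_COEFFICIENT,
) -> float:
    """Energy expended by an exercise bout: coefficient * MET * W * minutes."""
    if met < 0 or weight_kg < 0 or duration_min < 0:
        raise ValueError("MET, weight and duration must be nonnegative")
    return coefficient * met * weight_kg * duration_min


@dataclass(frozen=True)
class ExerciseEntry:
    """One logged exercise bout (MET intensity beta, duration in minutes)."""

    met: float
    duration_min: float
    timestamp: dt.datetime
    energy_kcal: float | None = None  # filled in when logged against a ledger

    def __post_init__(self) -> None:
        if self.met <= 0:
            raise ValueError("MET must be positive")
        if self.duration_min < 0:
            raise ValueError("duration must be nonnegative")


@dataclass(frozen=True)
class MealEntry:
    timestamp: dt.datetime
    meal: Meal
    energy_kcal: float
    macros: MacroTotals


@dataclass(frozen=True)
class DayLedger:
    """Diary and running energy balance for one calendar day.

    The deficit fields are derived properties so the telescoped identity
    ``calorie_deficit == Q + sum(E*) - sum(Z)`` always holds exactly.
    Overconsumption simply drives the deficit negative; it is recorded, never
    rejected, and downstream consumers floor it at zero.
    """

    date: dt.date
    requirement: DailyRequirement
    weight_kg: float
    meal_entries: tuple[MealEntry, ...] = ()
    exercise_entries: tuple[ExerciseEntry, ...] = ()
    met_coefficient: float = MET_COEFFICIENT

    @property
    def energy_consumed(self) -> float:
        return sum(e.energy_kcal for e in self.meal_entries)

    @property
    def energy_expended(self) -> float:
        return sum(e.energy_kcal or 0.0 for e in self.exercise_entries)

    @property
    def calorie_deficit(self) -> float:
        return self.requirement.calories_kcal + self.energy_expended - self.energy_consumed

    @property
    def macros_consumed(self) -> MacroTotals:
        totals = MacroTotals(0.0, 0.0, 0.0)
        for e in self.meal_entries:
            totals = totals + e.macros
        return totals

    @property
    def macro_deficits(self) -> MacroTotals:
        req = self.requirement.macros
        eaten = self.macros_consumed
        return MacroTotals(
            req.carbohydrate_g - eaten.carbohydrate_g,
            req.protein_g - eaten.protein_g,
            req.fat_g - eaten.fat_g,
        )


def new_day_ledger(
    profile: UserProfile,
    date: dt.date,
    pal: Mapping[ActivityLevel, float] | None = None,
    macro_split: tuple[float, float, float] = DEFAULT_MACRO_SPLIT,
    met_coefficient: float = MET_COEFFICIENT,
) -> DayLedger:
    """Open a fresh ledger for ``date`` with deficits equal to the requirement."""
    return DayLedger(
        date=date,
        requirement=daily_requirement(profile, pal=pal, macro_split=macro_split),
        weight_kg=profile.weight_kg,
        met_coefficient=met_coefficient,
    )


def log_meal(ledger: DayLedger, meal: Meal, timestamp: dt.datetime) -> DayLedger:
    """Append a meal; the deficit drops by the meal's energy and macros."""
    if timestamp.date() != ledger.date:
        raise ValueError(f"timestamp {timestamp} is outside ledger date {ledger.date}")
    entry = MealEntry(
        timestamp=timestamp,
        meal=meal,
        energy_kcal=meal_energy(meal),
        macros=meal_macros(meal),
    )
    return dataclasses.replace(ledger, meal_entries=ledger.meal_entries + (entry,))


def log_exercise(ledger: DayLedger, entry: ExerciseEntry) -> DayLedger:
    """Append an exercise bout; the deficit grows by its expenditure E*."""
    if entry.timestamp.date() != ledger.date:
        raise ValueError(f"timestamp {entry.timestamp} is outside ledger date {ledger.date}")
    energy = exercise_energy(
        entry.met, ledger.weight_kg, entry.duration_min, coefficient=ledger.met_coefficient
    )
    stamped = dataclasses.replace(entry, energy_kcal=energy)
    return dataclasses.replace(ledger, exercise_entries=ledger.exercise_entries + (stamped,))


def end_of_day_reset(
    ledger: DayLedger,
    next_date: dt.date,
    profile: UserProfile | None = None,
    pal: Mapping[ActivityLevel, float] | None = None,
) -> DayLedger:
    """Discard all residual balance and open a fresh ledger for ``next_date``.

    If ``profile`` is given (e.g. after a weight update) the requirement is
    recomputed from it; otherwise the previous requirement carries over.
    """
    if next_date <= ledger.date:
        raise ValueError(f"next date {next_date} is not after ledger date {ledger.date}")
    if profile is not None:
        requirement = daily_requirement(profile, pal=pal)
        weight = profile.weight_kg
    else:
        requirement = ledger.requirement
        weight = ledger.weight_kg
    return DayLedger(
        date=next_date,
        requirement=requirement,
        weight_kg=weight,
        met_coefficient=ledger.met_coefficient,
    )


# ---------------------------------------------------------------------------
# Serialization: profile as YAML/JSON block, ledger as JSON lines
# ---------------------------------------------------------------------------

def save_profile(profile: UserProfile, path: str | Path) -> None:
    path = Path(path)
    data = json.loads(profile.model_dump_json())
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_profile(path: str | Path) -> UserProfile:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return UserProfile.model_validate(data)


def _meal_payload(meal: Meal) -> list[dict]:
    return [
        {
            "food_id": c.food.id,
            "measure_label": c.measure_label,
            "weight_g": c.serving_weight_g,
            "n": c.n_servings,
        }
        for c in meal.components
    ]


def save_ledger(ledger: DayLedger, path: str | Path, append: bool = True) -> None:
    """Write ledger entries as JSON lines: one ``{ts, kind, payload}`` per line."""
    records = []
    for m in ledger.meal_entries:
        records.append(
            {"ts": m.timestamp.isoformat(), "kind": "meal", "payload": {"items": _meal_payload(m.meal)}}
        )
    for e in ledger.exercise_entries:
        records.append(
            {
                "ts": e.timestamp.isoformat(),
                "kind": "exercise",
                "payload": {"met": e.met, "duration_min": e.duration_min},
            }
        )
    records.sort(key=lambda r: r["ts"])
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def load_ledger(
    path: str | Path,
    profile: UserProfile,
    db: "FoodDatabase",
    date: dt.date,
    pal: Mapping[ActivityLevel, float] | None = None,
    met_coefficient: float = MET_COEFFICIENT,
) -> DayLedger:
    """Replay a JSON-lines diary into the ledger for one calendar day.

    Entries dated outside ``date`` are ignored (one ledger per date).
    """
    ledger = new_day_ledger(profile, date, pal=pal, met_coefficient=met_coefficient)
    path = Path(path)
    if not path.exists():
        return ledger
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{line_no}: malformed ledger line") from exc
    records.sort(key=lambda r: r["ts"])
    for rec in records:
        ts = dt.datetime.fromisoformat(rec["ts"])
        if ts.date() != date:
            continue
        if rec["kind"] == "meal":
            components = []
            for item in rec["payload"]["items"]:
                food = db.get(item["food_id"])
                components.append(
                    MealComponent(
                        food=food,
                        serving_weight_g=item["weight_g"],
                        n_servings=item["n"],
                        measure_label=item.get("measure_label"),
                    )
                )
            ledger = log_meal(ledger, Meal(components=tuple(components)), ts)
        elif rec["kind"] == "exercise":
            entry = ExerciseEntry(
                met=rec["payload"]["met"],
                duration_min=rec["payload"]["duration_min"],
                timestamp=ts,
            )
            ledger = log_exercise(ledger, entry)
        else:
            raise ValueError(f"unknown ledger entry kind {rec['kind']!r}")
    return ledger
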