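"""Genetic-algorithm meal search.

A chromosome is a candidate meal: one base component plus a tail of
additional components, each gene being a (food, serving measure, serving
count) triple.  The objective for a chromosome with energy Z against an
available calorie budget D is the slack

    f = D - Z,

which must be nonnegative for feasibility; the fitness of a feasible
chromosome is 1 / (1 + f), so the meal that best fills the remaining
deficit without exceeding it has maximal fitness.  Feasibility further
requires the meal's consumed macro grams to fit within the carbohydrate,
protein and fat deficits and — when the user's health status activates
them — a per-item glycemic-index bound and a total-cholesterol bound.
Infeasible chromosomes are not discarded: they receive the penalised
fitness 1 / (1 + |f| + PENALTY) so early populations can still evolve.

The generation loop is fully generational (each generation is replaced by
exactly ``population_size`` new offspring produced by selection, tail-swap
crossover, and gene-replacement mutation) with a best-ever feasible archive
kept outside the breeding population.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .food_db import FoodDatabase
from .nutrition import (
    FoodItem,
    Meal,
    MealComponent,
    component_cholesterol,
    component_energy,
    component_macros,
)

__all__ = [
    "PENALTY",
    "FLOAT_TOL",
    "DeficitState",
    "GAConfig",
    "EvaluatedChromosome",
    "GAResult",
    "init_population",
    "evaluate",
    "selection_probability",
    "tournament_select",
    "roulette_select",
    "crossover",
    "mutate",
    "evolve",
    "parameter_sweep",
    "write_generation_log",
]

#: Fitness penalty (kcal scale) added to |slack| for infeasible chromosomes.
PENALTY = 1e4
#: Tolerance for floating-point feasibility comparisons.
FLOAT_TOL = 1e-9


class DeficitState(BaseModel):
    """The remaining budgets a recommended meal must fit within."""

    model_config = ConfigDict(frozen=True)

    available_kcal: float = Field(ge=0)
    carb_deficit_g: float = Field(ge=0)
    protein_deficit_g: float = Field(ge=0)
    fat_deficit_g: float = Field(ge=0)
    gi_limit: Optional[float] = Field(default=None, gt=0)
    cholesterol_limit_mg: Optional[float] = Field(default=None, gt=0)


class GAConfig(BaseModel):
    """Control parameters for the evolutionary search."""

    model_config = ConfigDict(frozen=True)

    population_size: int = Field(default=30, ge=2)
    generations: int = Field(default=500, ge=1)
    crossover_prob: float = Field(default=0.65, ge=0, le=1)
    mutation_prob: float = Field(default=0.01, ge=0, le=1)
    tournament_size: int = Field(default=3, ge=1)
    max_additional_components: int = Field(default=5, ge=0)
    max_servings: int = Field(default=3, ge=1)
    seed: int = 0
    selection_mode: str = Field(default="tournament", pattern="^(tournament|roulette)$")
    #: stop after this many generations without improving the best feasible slack
    stall_generations: int = Field(default=50, ge=1)


@dataclass(frozen=True)
class EvaluatedChromosome:
    meal: Meal
    energy_kcal: float
    objective: float  # slack D - Z; negative when the meal overshoots
    feasible: bool
    fitness: float


@dataclass
class GAResult:
    """Outcome of one evolutionary run.

    ``best is None`` is the no-solution marker: no feasible meal was ever
    seen.  ``archive`` holds the best distinct feasible chromosomes by slack;
    ``log`` has one row per generation.
    """

    best: Optional[EvaluatedChromosome]
    log: pd.DataFrame
    archive: list[EvaluatedChromosome] = field(default_factory=list)
    converged_at: Optional[int] = None  # generation of last improvement

    def top(self, k: int) -> list[EvaluatedChromosome]:
        return self.archive[:k]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class _ComponentCache:
    """Memoises per-(food, measure, count) aggregates across evaluations."""

    def __init__(self) -> None:
        self._store: dict[tuple, tuple] = {}

    def stats(self, c: MealComponent) -> tuple:
        key = (c.food.id, c.measure_label, c.serving_weight_g, c.n_servings)
        hit = self._store.get(key)
        if hit is None:
            macros = component_macros(c)
            hit = (
                component_energy(c),
                macros.carbohydrate_g,
                macros.protein_g,
                macros.fat_g,
                component_cholesterol(c),
                c.food.nutrients.glycemic_index,
            )
            self._store[key] = hit
        return hit


def evaluate(
    meal: Meal,
    state: DeficitState,
    penalty: float = PENALTY,
    cache: _ComponentCache | None = None,
) -> EvaluatedChromosome:
    """Score a candidate meal against the deficit state.

    objective = available_kcal - Z (the slack); feasible iff the slack is
    nonnegative, macros fit componentwise, every item respects the GI bound
    when one is active, and total cholesterol stays strictly below the limit
    when one is active.
    """
    energy = carb = protein = fat = chol = 0.0
    gi_ok = True
    gi_limit = state.gi_limit
    for c in meal.components:
        if cache is not None:
            e, cg, pg, fg, ch, gi = cache.stats(c)
        else:
            macros = component_macros(c)
            e, cg, pg, fg = (
                component_energy(c),
                macros.carbohydrate_g,
                macros.protein_g,
                macros.fat_g,
            )
            ch = component_cholesterol(c)
            gi = c.food.nutrients.glycemic_index
        energy += e
        carb += cg
        protein += pg
        fat += fg
        chol += ch
        if gi_limit is not None and gi > gi_limit:
            gi_ok = False
    slack = state.available_kcal - energy
    feasible = (
        slack >= -FLOAT_TOL
        and carb <= state.carb_deficit_g + FLOAT_TOL
        and protein <= state.protein_deficit_g + FLOAT_TOL
        and fat <= state.fat_deficit_g + FLOAT_TOL
        and gi_ok
        and (state.cholesterol_limit_mg is None or chol < state.cholesterol_limit_mg)
    )
    fitness = 1.0 / (1.0 + slack) if feasible else 1.0 / (1.0 + abs(slack) + penalty)
    return EvaluatedChromosome(
        meal=meal, energy_kcal=energy, objective=slack, feasible=feasible, fitness=fitness
    )


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _random_component(
    foods: Sequence[FoodItem], config: GAConfig, rng: np.random.Generator
) -> MealComponent:
    food = foods[int(rng.integers(len(foods)))]
    measure = food.measures[int(rng.integers(len(food.measures)))]
    return MealComponent.model_construct(
        food=food,
        serving_weight_g=measure.weight_g,
        n_servings=int(rng.integers(1, config.max_servings + 1)),
        measure_label=measure.label,
    )


def _random_meal(
    foods: Sequence[FoodItem], config: GAConfig, rng: np.random.Generator
) -> Meal:
    n_tail = int(rng.integers(0, config.max_additional_components + 1))
    components = tuple(_random_component(foods, config, rng) for _ in range(1 + n_tail))
    return Meal.model_construct(components=components)


def init_population(
    db: FoodDatabase,
    config: GAConfig,
    state: DeficitState,
    rng: np.random.Generator,
    cache: _ComponentCache | None = None,
) -> list[EvaluatedChromosome]:
    """Randomly assemble and evaluate the initial population of meals."""
    if len(db) == 0:
        raise ValueError("food database is empty")
    foods = db.foods
    return [
        evaluate(_random_meal(foods, config, rng), state, cache=cache)
        for _ in range(config.population_size)
    ]


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def selection_probability(population: Sequence[EvaluatedChromosome]) -> np.ndarray:
    """Fitness-proportional selection probabilities, P[j] = fit[j] / sum(fit)."""
    if not population:
        raise ValueError("population is empty")
    fitness = np.array([c.fitness for c in population], dtype=float)
    return fitness / fitness.sum()


def tournament_select(
    population: Sequence[EvaluatedChromosome],
    tournament_size: int,
    rng: np.random.Generator,
) -> EvaluatedChromosome:
    """Fittest of ``tournament_size`` distinct uniform draws.

    Ties break toward lower meal energy, then earlier population index.
    """
    if tournament_size > len(population):
        raise ValueError(
            f"tournament size {tournament_size} exceeds population size {len(population)}"
        )
    idx = rng.choice(len(population), size=tournament_size, replace=False)
    best = None
    best_key = None
    for i in sorted(int(j) for j in idx):
        c = population[i]
        key = (-c.fitness, c.energy_kcal, i)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best  # type: ignore[return-value]


def roulette_select(
    population: Sequence[EvaluatedChromosome], rng: np.random.Generator
) -> EvaluatedChromosome:
    """Fitness-proportional (roulette-wheel) draw."""
    probs = selection_probability(population)
    return population[int(rng.choice(len(population), p=probs))]


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def crossover(
    parent1: Meal,
    parent2: Meal,
    crossover_prob: float,
    rng: np.random.Generator,
) -> tuple[Meal, Meal]:
    """Single-point whole-tail swap at the base/additional boundary.

    With probability ``crossover_prob`` the children exchange the parents'
    additional-component tails (base1+tail2, base2+tail1); otherwise they are
    copies of the parents.  The multiset of components across the pair is
    conserved either way.
    """
    if rng.random() >= crossover_prob:
        return parent1, parent2
    child1 = Meal.model_construct(components=(parent1.components[0],) + parent2.components[1:])
    child2 = Meal.model_construct(components=(parent2.components[0],) + parent1.components[1:])
    return child1, child2


def mutate(
    meal: Meal,
    mutation_prob: float,
    db: FoodDatabase | None,
    config: GAConfig,
    rng: np.random.Generator,
) -> Meal:
    """Replace randomly marked genes with new values.

    Each component contributes three mutable gene positions — its food (the
    composition values of the gene tuple), its serving measure (hence f), and
    its serving count N — plus one structural position per chromosome that
    adds or drops a tail component.  Each position is marked for mutation
    independently with probability ``mutation_prob``.  Food replacement and
    the structural gene are what supply new genetic material to the
    population: crossover only exchanges tails that already exist, so without
    them the search fixates on the initial population's foods and tail
    lengths.  ``db`` provides the pool for replacement draws; when ``None``
    only serving measure and count mutate.
    """
    if mutation_prob <= 0 or not meal.components:
        return meal
    foods = db.foods if db is not None else None
    components = list(meal.components)
    changed = False
    for i, comp in enumerate(components):
        food = comp.food
        new_weight, new_label = comp.serving_weight_g, comp.measure_label
        new_n = comp.n_servings
        if foods is not None and rng.random() < mutation_prob:
            food = foods[int(rng.integers(len(foods)))]
            measure = food.measures[int(rng.integers(len(food.measures)))]
            new_weight, new_label = measure.weight_g, measure.label
            changed = True
        if rng.random() < mutation_prob:
            measure = food.measures[int(rng.integers(len(food.measures)))]
            new_weight, new_label = measure.weight_g, measure.label
            changed = True
        if rng.random() < mutation_prob:
            new_n = int(rng.integers(1, config.max_servings + 1))
            changed = True
        if food is not comp.food or new_weight != comp.serving_weight_g or new_n != comp.n_servings:
            components[i] = MealComponent.model_construct(
                food=food,
                serving_weight_g=new_weight,
                n_servings=new_n,
                measure_label=new_label,
            )
    if foods is not None and rng.random() < mutation_prob:
        tail_len = len(components) - 1
        can_add = tail_len < config.max_additional_components
        can_drop = tail_len > 0
        if can_add and (not can_drop or rng.random() < 0.5):
            components.insert(
                1 + int(rng.integers(tail_len + 1)), _random_component(foods, config, rng)
            )
            changed = True
        elif can_drop:
            components.pop(1 + int(rng.integers(tail_len)))
            changed = True
    if not changed:
        return meal
    return Meal.model_construct(components=tuple(components))


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------

def _signature(meal: Meal) -> tuple:
    return tuple(
        sorted((c.food.id, c.serving_weight_g, c.n_servings) for c in meal.components)
    )


_LOG_COLUMNS = ["generation", "best_slack", "mean_fitness", "feasible_fraction"]


def evolve(db: FoodDatabase, state: DeficitState, config: GAConfig) -> GAResult:
    """Run the full evolutionary search and return the best feasible meal.

    The best-ever feasible chromosome is archived outside the generational
    replacement; generations are otherwise wholly replaced by offspring.
    Terminates early once the best feasible slack has not improved for
    ``config.stall_generations`` consecutive generations.  With a zero
    calorie budget nothing can fit, so the no-solution marker is returned
    immediately.
    """
    if len(db) == 0:
        raise ValueError("food database is empty")
    if state.available_kcal <= 0:
        return GAResult(best=None, log=pd.DataFrame(columns=_LOG_COLUMNS))

    rng = np.random.default_rng(config.seed)
    cache = _ComponentCache()
    population = init_population(db, config, state, rng, cache=cache)

    archive: dict[tuple, EvaluatedChromosome] = {}
    best: EvaluatedChromosome | None = None
    converged_at: int | None = None
    stall = 0
    log_rows: list[tuple] = []

    def absorb(generation: int, pop: Sequence[EvaluatedChromosome]) -> None:
        nonlocal best, converged_at, stall
        improved = False
        for c in pop:
            if not c.feasible:
                continue
            sig = _signature(c.meal)
            held = archive.get(sig)
            if held is None or c.objective < held.objective:
                archive[sig] = c
            if best is None or c.objective < best.objective - FLOAT_TOL:
                best = c
                improved = True
        if improved:
            converged_at = generation
            stall = 0
        else:
            stall += 1

    def log(generation: int, pop: Sequence[EvaluatedChromosome]) -> None:
        feasible = [c for c in pop if c.feasible]
        log_rows.append(
            (
                generation,
                best.objective if best is not None else np.nan,
                float(np.mean([c.fitness for c in pop])),
                len(feasible) / len(pop),
            )
        )

    absorb(0, population)
    log(0, population)

    def select(pop: Sequence[EvaluatedChromosome]) -> EvaluatedChromosome:
        if config.selection_mode == "roulette":
            return roulette_select(pop, rng)
        return tournament_select(pop, config.tournament_size, rng)

    for generation in range(1, config.generations + 1):
        offspring: list[EvaluatedChromosome] = []
        while len(offspring) < config.population_size:
            p1 = select(population)
            p2 = select(population)
            c1, c2 = crossover(p1.meal, p2.meal, config.crossover_prob, rng)
            for child in (c1, c2):
                if len(offspring) >= config.population_size:
                    break
                child = mutate(child, config.mutation_prob, db, config, rng)
                offspring.append(evaluate(child, state, cache=cache))
        population = offspring
        absorb(generation, population)
        log(generation, population)
        if stall >= config.stall_generations:
            break

    ranked = sorted(archive.values(), key=lambda c: (c.objective, c.energy_kcal))
    return GAResult(
        best=best,
        log=pd.DataFrame(log_rows, columns=_LOG_COLUMNS),
        archive=ranked,
        converged_at=converged_at,
    )


def write_generation_log(result: GAResult, path: str | Path) -> None:
    """Emit the per-generation log as CSV."""
    result.log.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def parameter_sweep(
    db: FoodDatabase,
    state: DeficitState,
    populations: Sequence[int] = (20, 30, 40, 50, 70, 100),
    mutation_rates: Sequence[float] = (0.001, 0.01, 0.08, 0.1, 0.5, 0.9),
    base_config: GAConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid-sweep population size x mutation rate, reporting convergence.

    Convergence is measured in generations (the generation at which the best
    feasible slack last improved) rather than wall-clock seconds, which are
    hardware-dependent.  Returns one row per grid cell with the achieved
    best slack and feasibility flag.
    """
    base = base_config or GAConfig()
    rows = []
    for pop_size in populations:
        for mut in mutation_rates:
            config = base.model_copy(
                update={
                    "population_size": pop_size,
                    "mutation_prob": mut,
                    "seed": seed + hash((pop_size, round(mut, 6))) % 100_000,
                }
            )
            result = evolve(db, state, config)
            rows.append(
                {
                    "population_size": pop_size,
                    "mutation_prob": mut,
                    "convergence_generation": result.converged_at,
                    "best_slack": result.best.objective if result.best else np.nan,
                    "found_feasible": result.best is not None,
                }
            )
    return pd.DataFrame(rows)
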