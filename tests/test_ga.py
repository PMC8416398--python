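"""Genetic-algorithm operators and the generation loop."""

import collections

import numpy as np
import pytest

import nutriga as ng
from nutriga.nutrition import Meal, MealComponent

from conftest import oracle_best, tiny_single_measure_db


def make_state(kcal=2000.0, carb=400.0, protein=150.0, fat=120.0, gi=None, chol=None):
    return ng.DeficitState(
        available_kcal=kcal,
        carb_deficit_g=carb,
        protein_deficit_g=protein,
        fat_deficit_g=fat,
        gi_limit=gi,
        cholesterol_limit_mg=chol,
    )


def component_multiset(meal):
    return collections.Counter(
        (c.food.id, c.serving_weight_g, c.n_servings) for c in meal.components
    )


class TestEvaluate:
    def test_slack_objective_and_feasibility(self, fixture_db):
        main, _ = ng.sample_recommended_meals(fixture_db)
        ec = ng.evaluate(main, make_state(kcal=2000.0))
        assert ec.energy_kcal == pytest.approx(826.86, abs=0.005)
        assert ec.objective == pytest.approx(2000 - 826.86, abs=0.005)
        assert ec.feasible
        assert ec.fitness == pytest.approx(1 / (1 + ec.objective))

    def test_exact_fill_has_maximal_fitness(self, fixture_db):
        main, _ = ng.sample_recommended_meals(fixture_db)
        energy = ng.meal_energy(main)
        ec = ng.evaluate(main, make_state(kcal=energy))
        assert ec.objective == pytest.approx(0.0, abs=1e-9)
        assert ec.fitness == pytest.approx(1.0)

    def test_high_gi_item_infeasible_for_diabetic_state(self, fixture_db):
        rice_ball = fixture_db.get("rice-ball")  # GI 70
        meal = Meal(
            components=(
                MealComponent(
                    food=rice_ball,
                    serving_weight_g=rice_ball.measures[0].weight_g,
                    n_servings=1,
                    measure_label=rice_ball.measures[0].label,
                ),
            )
        )
        assert ng.evaluate(meal, make_state(kcal=5000)).feasible
        assert not ng.evaluate(meal, make_state(kcal=5000, gi=55.0)).feasible

    def test_overshoot_is_penalized_not_rejected(self, fixture_db):
        main, _ = ng.sample_recommended_meals(fixture_db)
        ec = ng.evaluate(main, make_state(kcal=100.0))
        assert not ec.feasible
        assert ec.fitness < 1e-3  # penalty dominates
        assert ec.fitness > 0


class TestSelection:
    def test_probabilities_from_fitness(self, fixture_db):
        main, drinks = ng.sample_recommended_meals(fixture_db)
        # objectives 0 and 1 -> fitness 1 and 0.5 -> probabilities 2/3, 1/3
        pop = [
            ng.evaluate(main, make_state(kcal=ng.meal_energy(main))),
            ng.evaluate(drinks, make_state(kcal=ng.meal_energy(drinks) + 1.0)),
        ]
        probs = ng.selection_probability(pop)
        assert probs == pytest.approx([2 / 3, 1 / 3])

    def test_single_chromosome_probability_one(self, fixture_db):
        main, _ = ng.sample_recommended_meals(fixture_db)
        assert ng.selection_probability([ng.evaluate(main, make_state())]) == pytest.approx([1.0])

    def test_uniform_fitness_gives_uniform_probabilities(self, fixture_db):
        main, _ = ng.sample_recommended_meals(fixture_db)
        pop = [ng.evaluate(main, make_state()) for _ in range(4)]
        assert ng.selection_probability(pop) == pytest.approx([0.25] * 4)

    def test_full_tournament_returns_global_best(self, fixture_db):
        db = fixture_db
        rng = np.random.default_rng(0)
        state = make_state(kcal=1200)
        pop = ng.init_population(db, ng.GAConfig(seed=1, population_size=12), state, rng)
        winner = ng.tournament_select(pop, len(pop), rng)
        assert winner.fitness == max(c.fitness for c in pop)

    def test_tournament_larger_than_population_rejected(self, fixture_db):
        rng = np.random.default_rng(0)
        pop = ng.init_population(
            fixture_db, ng.GAConfig(seed=1, population_size=5), make_state(), rng
        )
        with pytest.raises(ValueError):
            ng.tournament_select(pop, 6, rng)

    def test_tournament_of_one_is_uniform_draw(self, fixture_db):
        rng = np.random.default_rng(5)
        pop = ng.init_population(
            fixture_db, ng.GAConfig(seed=2, population_size=8), make_state(), rng
        )
        seen = {id(ng.tournament_select(pop, 1, rng)) for _ in range(200)}
        assert len(seen) > 4  # draws spread over the population, not just the best


class TestCrossover:
    def test_published_child_totals(self, fixture_db):
        x1, x2 = ng.crossover_example_parents(fixture_db)
        c1, c2 = ng.crossover(x1, x2, 1.0, np.random.default_rng(0))
        assert ng.meal_energy(c1) == pytest.approx(1717.21, abs=0.005)
        assert ng.meal_energy(c2) == pytest.approx(2537.63, abs=0.005)
        # base genes retained, tails exchanged
        assert c1.base.food.id == "kenkey" and c2.base.food.id == "rice-ball"

    def test_conserves_component_multiset(self, fixture_db):
        x1, x2 = ng.crossover_example_parents(fixture_db)
        c1, c2 = ng.crossover(x1, x2, 1.0, np.random.default_rng(1))
        assert component_multiset(c1) + component_multiset(c2) == component_multiset(
            x1
        ) + component_multiset(x2)

    def test_zero_probability_returns_parents(self, fixture_db):
        x1, x2 = ng.crossover_example_parents(fixture_db)
        c1, c2 = ng.crossover(x1, x2, 0.0, np.random.default_rng(2))
        assert c1 is x1 and c2 is x2

    def test_tailless_parents_unchanged(self, fixture_db):
        x1, x2 = ng.crossover_example_parents(fixture_db)
        b1 = Meal(components=(x1.components[0],))
        b2 = Meal(components=(x2.components[0],))
        c1, c2 = ng.crossover(b1, b2, 1.0, np.random.default_rng(3))
        assert component_multiset(c1) == component_multiset(b1)
        assert component_multiset(c2) == component_multiset(b2)


class TestMutate:
    def test_zero_probability_is_identity(self, fixture_db):
        x1, _ = ng.crossover_example_parents(fixture_db)
        out = ng.mutate(x1, 0.0, fixture_db, ng.GAConfig(), np.random.default_rng(0))
        assert out is x1

    def test_probability_one_resamples_every_position(self, fixture_db):
        x1, _ = ng.crossover_example_parents(fixture_db)
        rng = np.random.default_rng(4)
        out = ng.mutate(x1, 1.0, fixture_db, ng.GAConfig(max_servings=3), rng)
        assert out.components  # still a valid meal
        for c in out.components:
            assert c.food.id in fixture_db
            assert 1 <= c.n_servings <= 3
            assert c.food.find_measure(weight_g=c.serving_weight_g) is not None

    def test_reproducible_under_seeded_rng(self, fixture_db):
        x1, _ = ng.crossover_example_parents(fixture_db)
        a = ng.mutate(x1, 0.5, fixture_db, ng.GAConfig(), np.random.default_rng(7))
        b = ng.mutate(x1, 0.5, fixture_db, ng.GAConfig(), np.random.default_rng(7))
        assert component_multiset(a) == component_multiset(b)

    def test_without_database_only_servings_change(self, fixture_db):
        x1, _ = ng.crossover_example_parents(fixture_db)
        out = ng.mutate(x1, 1.0, None, ng.GAConfig(), np.random.default_rng(8))
        assert [c.food.id for c in out.components] == [c.food.id for c in x1.components]


class TestInitPopulation:
    def test_size_and_determinism(self, fixture_db):
        config = ng.GAConfig(seed=1, population_size=30)
        state = make_state()
        pop_a = ng.init_population(fixture_db, config, state, np.random.default_rng(9))
        pop_b = ng.init_population(fixture_db, config, state, np.random.default_rng(9))
        assert len(pop_a) == 30
        assert [component_multiset(c.meal) for c in pop_a] == [
            component_multiset(c.meal) for c in pop_b
        ]

    def test_single_food_no_tail_forces_singletons(self):
        db = tiny_single_measure_db(1, seed=0)
        config = ng.GAConfig(seed=1, population_size=10, max_additional_components=0)
        pop = ng.init_population(db, config, make_state(), np.random.default_rng(0))
        assert all(len(c.meal.components) == 1 for c in pop)

    def test_empty_database_rejected(self, fixture_db):
        empty = ng.FoodDatabase([])
        with pytest.raises(ValueError):
            ng.init_population(empty, ng.GAConfig(), make_state(), np.random.default_rng(0))


class TestEvolve:
    def test_deterministic_under_seed(self, fixture_db):
        state = make_state(kcal=1192.86, carb=123.25, protein=50.5, fat=40.67)
        config = ng.GAConfig(seed=3, generations=60, stall_generations=20)
        a = ng.evolve(fixture_db, state, config)
        b = ng.evolve(fixture_db, state, config)
        assert a.best is not None
        assert a.best.objective == b.best.objective
        assert component_multiset(a.best.meal) == component_multiset(b.best.meal)

    def test_zero_budget_returns_no_solution_marker(self, fixture_db):
        state = make_state(kcal=0.0, carb=0.0, protein=0.0, fat=0.0)
        assert ng.evolve(fixture_db, state, ng.GAConfig(seed=1)).best is None

    def test_returned_solution_respects_all_budgets(self, fixture_db):
        rng = np.random.default_rng(11)
        for _ in range(25):
            state = make_state(
                kcal=float(rng.uniform(100, 2500)),
                carb=float(rng.uniform(10, 400)),
                protein=float(rng.uniform(10, 150)),
                fat=float(rng.uniform(5, 120)),
                gi=55.0 if rng.random() < 0.5 else None,
            )
            config = ng.GAConfig(
                seed=int(rng.integers(2**31)), population_size=20, generations=25,
                stall_generations=10,
            )
            result = ng.evolve(fixture_db, state, config)
            if result.best is None:
                continue
            meal = result.best.meal
            assert ng.meal_energy(meal) <= state.available_kcal + 1e-6
            macros = ng.meal_macros(meal)
            assert macros.carbohydrate_g <= state.carb_deficit_g + 1e-6
            assert macros.protein_g <= state.protein_deficit_g + 1e-6
            assert macros.fat_g <= state.fat_deficit_g + 1e-6
            if state.gi_limit is not None:
                assert ng.gi_within_limit(meal, state.gi_limit)

    def test_never_beats_exhaustive_oracle(self):
        for seed in range(5):
            db = tiny_single_measure_db(4, seed=seed)
            state = make_state(kcal=1200 + 100 * seed)
            config = ng.GAConfig(
                seed=seed, max_servings=2, max_additional_components=2,
                generations=80, stall_generations=30,
            )
            result = ng.evolve(db, state, config)
            opt = oracle_best(db, state, 2, 2)
            if result.best is not None:
                assert opt is not None
                assert result.best.objective >= opt.objective - 1e-9

    def test_generation_log_schema(self, fixture_db, tmp_path):
        state = make_state(kcal=1500)
        result = ng.evolve(fixture_db, state, ng.GAConfig(seed=5, generations=10))
        assert list(result.log.columns) == [
            "generation", "best_slack", "mean_fitness", "feasible_fraction",
        ]
        assert (result.log["feasible_fraction"] <= 1).all()
        out = tmp_path / "log.csv"
        ng.write_generation_log(result, out)
        assert out.read_text().startswith("generation,")


def test_parameter_sweep_reports_convergence_generations(fixture_db):
    state = make_state(kcal=1200, carb=200, protein=80, fat=60)
    frame = ng.parameter_sweep(
        fixture_db,
        state,
        populations=(10, 20),
        mutation_rates=(0.01, 0.1),
        base_config=ng.GAConfig(generations=30, stall_generations=10),
        seed=1,
    )
    assert len(frame) == 4
    assert frame["found_feasible"].all()
    assert frame["convergence_generation"].notna().all()
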