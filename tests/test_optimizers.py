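"""AOS/BAOS population dynamics, acceptance bookkeeping and baselines."""

import itertools
import math

import numpy as np
import pytest

from baoscnn.benchmarks import benchmark, benchmark_space
from baoscnn.optimizers import (
    Electron,
    ObjectiveError,
    OptimizerParams,
    Population,
    aos_step,
    assign_layers,
    baos_step,
    binding,
    evaluate,
    initialize,
    optimize,
    random_search,
)
from baoscnn.search_space import HyperparameterSpec, SearchSpace


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


@pytest.fixture
def box5():
    return benchmark_space("sphere", 5)


class TestInitializeEvaluate:
    def test_population_of_thirty_in_bounds(self, table1_space, rng):
        pop = initialize(table1_space, 30, rng)
        lo, hi = table1_space.embedded_bounds()
        assert pop.m == 30
        for e in pop.electrons:
            assert np.all(e.position >= lo) and np.all(e.position <= hi)
            assert e.energy is None and e.limit_counter == 0

    def test_same_seed_same_population(self, box5):
        a = initialize(box5, 10, np.random.default_rng(3))
        b = initialize(box5, 10, np.random.default_rng(3))
        assert all(
            np.array_equal(x.position, y.position)
            for x, y in zip(a.electrons, b.electrons)
        )

    def test_degenerate_single_electron(self, box5, rng):
        assert initialize(box5, 1, rng).m == 1

    def test_invalid_size_rejected(self, box5, rng):
        with pytest.raises(ValueError):
            initialize(box5, 0, rng)

    def test_best_energy_is_population_minimum(self, box5, rng):
        pop = evaluate(initialize(box5, 20, rng), sphere)
        assert pop.best_energy == min(e.energy for e in pop.electrons)

    def test_lowest_energy_electron_selected(self):
        pop = Population(
            electrons=[Electron(np.zeros(2)), Electron(np.ones(2))]
        )
        energies = iter([3.0, 1.0])
        evaluate(pop, lambda x: next(energies))
        assert pop.best_energy == 1.0
        assert np.array_equal(pop.best_position, np.ones(2))

    def test_non_finite_objective_reported_with_position(self, box5, rng):
        pop = initialize(box5, 2, rng)
        with pytest.raises(ObjectiveError):
            evaluate(pop, lambda x: float("nan"))


class TestLayers:
    def test_single_layer_holds_everyone(self, box5, rng):
        pop = evaluate(initialize(box5, 12, rng), sphere)
        layers = assign_layers(pop, 1, rng)
        assert layers.n_layers == 1
        assert np.all(layers.layer_of == 1)

    def test_every_electron_in_exactly_one_valid_layer(self, box5, rng):
        pop = evaluate(initialize(box5, 30, rng), sphere)
        for _ in range(20):
            layers = assign_layers(pop, 5, rng)
            assert layers.layer_of.shape == (30,)
            assert layers.layer_of.min() >= 1
            assert layers.layer_of.max() <= layers.n_layers

    def test_best_electron_always_innermost(self, box5, rng):
        pop = evaluate(initialize(box5, 30, rng), sphere)
        best = int(np.argmin([e.energy for e in pop.electrons]))
        for _ in range(20):
            assert assign_layers(pop, 5, rng).layer_of[best] == 1


class TestBinding:
    def test_identical_electrons_collapse_to_their_state(self, rng):
        pos = np.array([0.5, -0.5])
        pop = Population(electrons=[Electron(pos.copy()) for _ in range(4)])
        evaluate(pop, sphere)
        layers = assign_layers(pop, 3, rng)
        record = binding(pop, layers)
        assert np.allclose(record.bs, pos)
        assert record.be == pytest.approx(sphere(pos))

    def test_single_electron_degenerate(self, rng):
        pop = evaluate(Population(electrons=[Electron(np.array([1.0, 2.0]))]), sphere)
        record = binding(pop, assign_layers(pop, 5, rng))
        assert np.array_equal(record.bs, np.array([1.0, 2.0]))
        assert np.array_equal(record.le, np.array([1.0, 2.0]))

    def test_layer_binding_energy_is_the_mean(self, rng):
        pop = Population(
            electrons=[
                Electron(np.array([np.sqrt(0.2), 0.0])),
                Electron(np.array([np.sqrt(0.4), 0.0])),
            ]
        )
        evaluate(pop, sphere)
        layers = assign_layers(pop, 1, rng)
        record = binding(pop, layers)
        assert record.layer_be[0] == pytest.approx(0.3)


class TestStepBookkeeping:
    def _ready(self, space, m, rng, objective):
        pop = evaluate(initialize(space, m, rng), objective)
        layers = assign_layers(pop, 3, rng)
        return pop, binding(pop, layers), layers

    def test_improving_moves_reset_counters(self, box5):
        rng = np.random.default_rng(0)
        # strictly decreasing objective: every proposal is an improvement
        counter = itertools.count()
        objective = lambda x: -float(next(counter))  # noqa: E731
        pop, bind, layers = self._ready(box5, 6, rng, objective)
        for e in pop.electrons:
            e.limit_counter = 3
        aos_step(pop, bind, layers, OptimizerParams(m=6), rng, box5, objective)
        assert all(e.limit_counter == 0 for e in pop.electrons)

    def test_non_improving_moves_increment_counters(self, box5):
        rng = np.random.default_rng(0)
        objective = lambda x: 1.0  # flat: no strict improvement possible  # noqa: E731
        pop, bind, layers = self._ready(box5, 6, rng, objective)
        aos_step(pop, bind, layers, OptimizerParams(m=6), rng, box5, objective)
        assert all(e.limit_counter == 1 for e in pop.electrons)

    def test_all_positions_in_bounds_after_step(self, box5):
        rng = np.random.default_rng(1)
        pop, bind, layers = self._ready(box5, 10, rng, sphere)
        baos_step(pop, bind, layers, OptimizerParams(m=10), rng, box5, sphere)
        lo, hi = box5.embedded_bounds()
        for e in pop.electrons:
            assert np.all(e.position >= lo) and np.all(e.position <= hi)

    def test_stagnant_electron_relocated_and_reset(self, box5):
        rng = np.random.default_rng(2)
        pop, bind, layers = self._ready(box5, 4, rng, sphere)
        target = pop.electrons[2]
        target.limit_counter = 99
        old = target.position.copy()
        baos_step(
            pop, bind, layers, OptimizerParams(m=4, limit_threshold=5), rng, box5, sphere
        )
        assert not np.array_equal(target.position, old)
        assert target.limit_counter == 0

    def test_photon_rates_stay_in_unit_interval(self, box5):
        rng = np.random.default_rng(3)
        pop, bind, layers = self._ready(box5, 10, rng, sphere)
        for _ in range(30):
            layers = assign_layers(pop, 5, rng)
            bind = binding(pop, layers)
            baos_step(pop, bind, layers, OptimizerParams(m=10), rng, box5, sphere)
        assert all(0.0 <= e.photon_rate <= 1.0 for e in pop.electrons)

    def test_baos_reduces_to_aos_without_boost_features(self, box5):
        params_a = OptimizerParams(m=8, max_iterations=15, n_runs=1, algorithm="aos", seed=7)
        params_b = OptimizerParams(
            m=8,
            max_iterations=15,
            n_runs=1,
            algorithm="baos",
            seed=7,
            limit_threshold=math.inf,
            pr_update=False,
        )
        ra = optimize(sphere, box5, params_a)
        rb = optimize(sphere, box5, params_b)
        assert ra.trace == rb.trace
        assert np.array_equal(ra.best_position, rb.best_position)


class TestOptimize:
    @pytest.mark.parametrize("algorithm", ["aos", "baos", "random"])
    def test_trace_monotone_and_improving(self, algorithm, box5):
        params = OptimizerParams(
            m=10, max_iterations=20, n_runs=1, algorithm=algorithm, seed=1
        )
        result = optimize(sphere, box5, params)
        assert result.trace[-1] < result.trace[0]
        assert all(a >= b for a, b in zip(result.trace, result.trace[1:]))

    @pytest.mark.parametrize("algorithm", ["aos", "baos", "random"])
    def test_seeded_bitwise_reproducibility(self, algorithm, box5):
        params = OptimizerParams(
            m=8, max_iterations=10, n_runs=2, algorithm=algorithm, seed=11
        )
        r1 = optimize(sphere, box5, params)
        r2 = optimize(sphere, box5, params)
        assert r1.trace == r2.trace
        assert np.array_equal(r1.best_position, r2.best_position)
        assert [rec.trace for rec in r1.per_run] == [rec.trace for rec in r2.per_run]

    @pytest.mark.parametrize("algorithm", ["aos", "baos"])
    def test_budget_accounting_exact(self, algorithm, box5):
        calls = []
        objective = lambda x: (calls.append(1), sphere(x))[1]  # noqa: E731
        params = OptimizerParams(
            m=7, max_iterations=9, n_runs=2, algorithm=algorithm, seed=0
        )
        result = optimize(objective, box5, params)
        assert result.evaluations == len(calls)
        assert result.evaluations == 2 * 7 * (1 + 9)

    def test_ten_run_protocol_reports_ten_records(self, box5):
        params = OptimizerParams(m=4, max_iterations=3, n_runs=10, seed=5)
        assert len(optimize(sphere, box5, params).per_run) == 10

    def test_sphere_converges_below_millinat_at_kilobudget(self, box5):
        bests = []
        for seed in range(10):
            params = OptimizerParams(
                m=5, max_iterations=199, n_runs=1, algorithm="baos", seed=seed
            )
            bests.append(optimize(sphere, box5, params).best_energy)
        assert np.median(bests) < 1e-3

    def test_finds_enumerated_optimum_of_small_discrete_space(self):
        space = SearchSpace(
            specs=tuple(
                HyperparameterSpec(f"h{j}", "discrete", categories=(0, 1, 2, 3))
                for j in range(3)
            )
        )
        table_rng = np.random.default_rng(42)
        table = {
            k: table_rng.random() for k in itertools.product(range(4), repeat=3)
        }
        true_opt = min(table.values())  # exhaustive enumeration oracle

        def objective(pos):
            a = space.decode(pos)
            return table[(a["h0"], a["h1"], a["h2"])]

        hits = 0
        for seed in range(20):
            params = OptimizerParams(
                m=20, max_iterations=14, n_runs=1, algorithm="baos", seed=seed
            )
            result = optimize(objective, space, params)
            hits += abs(result.best_energy - true_opt) < 1e-12
        assert hits >= 19  # >= 95% of 20 seeds


class TestRandomSearch:
    def test_unit_budget_returns_single_sample(self, box5):
        result = random_search(sphere, box5, 1, np.random.default_rng(0))
        assert result.evaluations == 1
        assert result.trace == [result.best_energy]

    def test_seeded_determinism(self, box5):
        r1 = random_search(sphere, box5, 50, np.random.default_rng(9))
        r2 = random_search(sphere, box5, 50, np.random.default_rng(9))
        assert r1.trace == r2.trace

    def test_budget_spent_exactly(self, box5):
        calls = []
        objective = lambda x: (calls.append(1), sphere(x))[1]  # noqa: E731
        result = random_search(objective, box5, 37, np.random.default_rng(0))
        assert result.evaluations == 37 == len(calls)
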