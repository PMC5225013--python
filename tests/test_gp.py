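"""Evolutionary engine: initialization, selection, evolution contracts."""

import numpy as np
import pytest

import gpkin.expressions as ex
from gpkin import (GPConfig, evolve, init_population,
                   median_fitness_trajectory, tournament_select, variety)
from gpkin.gp import SymbolicRegressor, random_tree


class TestConfig:
    def test_default_configuration(self):
        cfg = GPConfig()
        assert cfg.population_size == 500
        assert cfg.generations == 50
        assert cfg.p_crossover == 0.9
        assert cfg.p_mutation == 0.1
        assert cfg.elitism is True
        assert cfg.depth_limit == 28
        assert (cfg.init_depth_min, cfg.init_depth_max) == (2, 6)
        assert set(cfg.constants) == {1.0, 5.0, 10.0, 100.0, 1000.0}

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            GPConfig(p_crossover=1.2)
        with pytest.raises(ValueError):
            GPConfig(population_size=0)


class TestInitPopulation:
    def test_population_size_and_validity(self):
        cfg = GPConfig(population_size=500, seed=0)
        pop = init_population(cfg)
        assert len(pop) == 500
        for tree in pop:
            d = tree.depth()
            assert cfg.init_depth_min <= d <= cfg.init_depth_max
            # Node construction enforces arity; round-trip proves structure
            assert ex.parse(ex.serialize(tree)) == tree

    def test_half_and_half_method_allocation(self):
        # the ramp alternates full/grow blocks; full-method trees are
        # perfect (every leaf at the assigned depth), so at least half the
        # population must sit exactly at its assigned ramp depth
        cfg = GPConfig(population_size=1000, seed=1)
        pop = init_population(cfg)
        depths = list(range(cfg.init_depth_min, cfg.init_depth_max + 1))
        exact = 0
        for i, tree in enumerate(pop):
            assigned = depths[i % len(depths)]
            is_full_block = (i // len(depths)) % 2 == 0
            if is_full_block:
                assert tree.depth() == assigned
            exact += tree.depth() == assigned
        assert exact >= 500


class TestTournament:
    def setup_method(self):
        self.rng = np.random.default_rng(2)
        cfg = GPConfig(population_size=1)
        self.pop = [random_tree(self.rng, 3, "grow", cfg) for _ in range(8)]
        self.fitness = np.array([5.0, 3.0, 8.0, 1.0, 9.0, 2.0, 7.0, 4.0])

    def test_full_size_tournament_returns_global_best(self):
        for _ in range(20):
            i = tournament_select(self.pop, self.fitness, size=200,
                                  rng=self.rng)
            assert i == 3

    def test_size_one_is_uniform_draw(self):
        counts = np.zeros(8)
        n = 40_000
        for _ in range(n):
            counts[tournament_select(self.pop, self.fitness, 1,
                                     self.rng)] += 1
        np.testing.assert_allclose(counts / n, np.full(8, 1 / 8), atol=0.01)

    def test_size_two_matches_analytic_selection_pressure(self):
        # with replacement, P(winner has fitness rank r of N) =
        # ((N-r+1)^2 - (N-r)^2) / N^2 for distinct fitness values
        N = 8
        ranks = np.argsort(np.argsort(self.fitness))  # 0 = best? no: asc
        n = 60_000
        counts = np.zeros(N)
        for _ in range(n):
            counts[tournament_select(self.pop, self.fitness, 2,
                                     self.rng)] += 1
        emp = counts / n
        for i in range(N):
            r = int(ranks[i]) + 1  # 1 = lowest (best) fitness
            expected = ((N - r + 1) ** 2 - (N - r) ** 2) / N ** 2
            assert emp[i] == pytest.approx(expected, abs=0.012)


@pytest.fixture(scope="module")
def small_run():
    import pandas as pd
    from gpkin import UptakeDataset
    rows = [(c, t, 2.0 * c * t, 1) for c in (5, 10, 20)
            for t in (3, 9, 15)]
    data = UptakeDataset(pd.DataFrame(
        rows, columns=["c0_uM", "t_min", "value", "replicate"]))
    cfg = GPConfig(population_size=25, generations=8)
    return data, cfg, evolve(data, cfg, seed=13)


class TestEvolve:
    def test_elitism_best_fitness_non_increasing(self, small_run):
        _, _, arc = small_run
        best = np.array([f for _, f in arc.best_per_gen])
        assert np.all(np.diff(best) <= 1e-12)
        assert np.all(np.diff(arc.best_so_far()) <= 0)

    def test_every_individual_respects_depth_limit(self, small_run):
        data, _, _ = small_run
        cfg = GPConfig(population_size=20, generations=5, depth_limit=6)
        arc = evolve(data, cfg, seed=3)
        assert all(t.depth() <= 6 for t in arc.final_population)

    def test_fixed_seed_is_bitwise_reproducible(self, small_run):
        data, cfg, arc = small_run
        again = evolve(data, cfg, seed=13)
        assert arc.to_json() == again.to_json()

    def test_archive_is_complete(self, small_run):
        _, cfg, arc = small_run
        assert len(arc.fitness_history) == cfg.generations
        assert len(arc.best_per_gen) == cfg.generations
        assert len(arc.final_population) == cfg.population_size
        assert arc.best_tree is not None

    def test_median_trajectory_matches_recomputation(self, small_run):
        _, _, arc = small_run
        med = median_fitness_trajectory(arc)
        for g, vals in enumerate(arc.fitness_history):
            finite = vals[np.isfinite(vals)]
            assert med[g] == pytest.approx(np.median(finite))

    def test_final_median_below_initial_median(self, small_run):
        _, _, arc = small_run
        med = median_fitness_trajectory(arc)
        assert med[-1] < med[0]


class TestVariety:
    def test_limits(self):
        rng = np.random.default_rng(0)
        cfg = GPConfig(population_size=1)
        tree = random_tree(rng, 3, "grow", cfg)
        assert variety([tree.copy() for _ in range(10)]) == pytest.approx(0.1)
        distinct = [ex.parse(f"{float(i)}*C0") for i in range(10)]
        assert variety(distinct) == 1.0

    def test_matches_brute_force_pairwise_comparison(self):
        rng = np.random.default_rng(1)
        cfg = GPConfig(population_size=1)
        pop = [random_tree(rng, 3, "grow", cfg) for _ in range(20)]
        pop += [pop[0].copy(), pop[3].copy(), pop[3].copy()]
        unique = []
        for t in pop:
            if not any(t == u for u in unique):
                unique.append(t)
        assert variety(pop) == pytest.approx(len(unique) / len(pop))


class TestSymbolicRegressorEstimator:
    def test_sklearn_contract_and_recovery(self):
        from sklearn.base import clone
        est = SymbolicRegressor(population_size=30, generations=12,
                                random_state=7)
        assert clone(est).get_params() == est.get_params()
        c0, t = np.meshgrid([5.0, 10.0, 20.0], [3.0, 9.0, 15.0])
        X = np.column_stack([c0.ravel(), t.ravel()])
        y = 2.0 * X[:, 0] * X[:, 1]
        est.fit(X, y)
        assert est.best_fitness_ < 1e-3
        np.testing.assert_allclose(est.predict(X), y, atol=1e-2)
        assert isinstance(est.expression_, str)
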