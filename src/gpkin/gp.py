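"""The evolutionary search over expression trees.

A generational genetic-programming loop with:

* ramped-half-and-half initialization (depths 2..6, half "full" / half
  "grow" trees per depth stratum),
* tournament selection (default size 2; ties go to the smaller tree, then
  to a random draw),
* subtree crossover (p = 0.9) and subtree mutation (p = 0.1, replacement
  subtree grown to depth <= 4),
* elitism (the best individual is copied unchanged every generation),
* a hard depth limit (28); offspring exceeding it are rejected and the
  parent survives instead,
* Lamarckian refitting: every individual's constants are refit to the
  training data and the improved values are written back into its genotype
  before fitness is recorded,
* jackknife generalization error as the fitness (lower is better);
  individuals that are non-finite on the data receive a worst-rank
  sentinel rather than being removed, keeping the population size constant.

Fitness evaluations are cached by genotype string: the jackknife fitness
costs N + 1 nonlinear fits per individual, and converged populations are
full of duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import expressions as ex
from .datasets import UptakeDataset
from .exceptions import DegenerateRunError
from .fitting import ArrayDataset, TreeModel, fit
from .jackknife import WORST_FITNESS, jackknife

__all__ = ["GPConfig", "RunArchive", "init_population", "random_tree",
           "tournament_select", "crossover", "mutate", "evolve", "run_many",
           "variety", "median_fitness_trajectory", "SymbolicRegressor"]


@dataclass(frozen=True)
class GPConfig:
    """Search configuration; defaults are the package's standard settings."""

    population_size: int = 500
    generations: int = 50
    p_crossover: float = 0.9
    p_mutation: float = 0.1
    elitism: bool = True
    init_depth_min: int = 2
    init_depth_max: int = 6
    depth_limit: int = 28
    tournament_size: int = 2
    mutation_max_depth: int = 4
    n_runs: int = 50
    seed: int | None = None
    objective: str = "l2"          # parameter-fitting / aggregation form
    fit_restarts: int = 2          # restarts inside the fitness loop
    max_nfev: int = 80             # per-local-fit function-evaluation cap
    p_terminal_constant: float = 0.5   # constant vs variable at a leaf
    constants: tuple = ex.DEFAULT_CONSTANTS

    def __post_init__(self):
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("sizes must be >= 1")
        if self.init_depth_min < 1 or self.init_depth_max < self.init_depth_min:
            raise ValueError("bad init depth ramp")


@dataclass
class RunArchive:
    """Per-run provenance: everything needed to re-derive the diagnostics."""

    config: GPConfig
    seed: int | None
    fitness_history: list = field(default_factory=list)   # one array per gen
    best_per_gen: list = field(default_factory=list)      # (expr, fitness)
    final_population: list = field(default_factory=list)  # Node objects
    best_tree: ex.Node | None = None
    best_fitness: float = WORST_FITNESS

    def best_so_far(self) -> np.ndarray:
        """Monotone non-increasing best-fitness trajectory."""
        vals = np.array([f for _, f in self.best_per_gen])
        return np.minimum.accumulate(vals)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "fitness_history": [list(map(float, g))
                                for g in self.fitness_history],
            "best_per_gen": [[e, float(f)] for e, f in self.best_per_gen],
            "final_population": [ex.serialize(t)
                                 for t in self.final_population],
            "best_tree": (ex.serialize(self.best_tree)
                          if self.best_tree is not None else None),
            "best_fitness": float(self.best_fitness),
        })


# ---------------------------------------------------------------------------
# Random tree construction
# ---------------------------------------------------------------------------

_ALL_FUNCS = ex.UNARY_FUNCTIONS + ex.BINARY_FUNCTIONS


def _random_terminal(rng: np.random.Generator, config: GPConfig) -> ex.Node:
    if rng.random() < config.p_terminal_constant:
        return ex.constant(rng.choice(config.constants))
    return ex.variable(ex.VARIABLES[rng.integers(len(ex.VARIABLES))])


def random_tree(rng: np.random.Generator, max_depth: int,
                method: str = "grow", config: GPConfig = GPConfig()) -> ex.Node:
    """One random tree: ``"full"`` branches to exactly ``max_depth`` levels,
    ``"grow"`` may stop early at any leaf."""
    def build(depth_left: int) -> ex.Node:
        if depth_left <= 1:
            return _random_terminal(rng, config)
        if method == "grow" and rng.random() < 0.3:
            return _random_terminal(rng, config)
        name = _ALL_FUNCS[rng.integers(len(_ALL_FUNCS))]
        arity = 1 if name in ex.UNARY_FUNCTIONS else 2
        return ex.func(name, *[build(depth_left - 1) for _ in range(arity)])
    if max_depth <= 1:
        return _random_terminal(rng, config)
    # guarantee a non-trivial root for depth >= 2
    name = _ALL_FUNCS[rng.integers(len(_ALL_FUNCS))]
    arity = 1 if name in ex.UNARY_FUNCTIONS else 2
    return ex.func(name, *[build(max_depth - 1) for _ in range(arity)])


def init_population(config: GPConfig,
                    rng: np.random.Generator | None = None) -> list[ex.Node]:
    """Ramped half-and-half: depths cycle over the ramp, alternating
    full- and grow-method construction."""
    rng = rng or np.random.default_rng(config.seed)
    depths = list(range(config.init_depth_min, config.init_depth_max + 1))
    population = []
    for i in range(config.population_size):
        depth = depths[i % len(depths)]
        method = "full" if (i // len(depths)) % 2 == 0 else "grow"
        population.append(random_tree(rng, depth, method, config))
    return population


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _random_path(tree: ex.Node, rng: np.random.Generator):
    paths = [p for p, _ in tree.iter_paths()]
    return paths[rng.integers(len(paths))]


def crossover(a: ex.Node, b: ex.Node,
              rng: np.random.Generator) -> tuple[ex.Node, ex.Node]:
    """Swap uniformly chosen subtrees between two parents."""
    pa, pb = _random_path(a, rng), _random_path(b, rng)
    sa, sb = a.node_at(pa), b.node_at(pb)
    return a.replace_at(pa, sb.copy()), b.replace_at(pb, sa.copy())


def mutate(tree: ex.Node, rng: np.random.Generator,
           config: GPConfig = GPConfig()) -> ex.Node:
    """Replace a uniformly chosen node's subtree with a fresh grown one."""
    path = _random_path(tree, rng)
    sub = random_tree(rng, int(rng.integers(1, config.mutation_max_depth + 1)),
                      "grow", config)
    return tree.replace_at(path, sub)


def tournament_select(population: list[ex.Node], fitness: np.ndarray,
                      size: int, rng: np.random.Generator) -> int:
    """Index of the tournament winner.

    ``size`` contestants are drawn uniformly with replacement; the lowest
    fitness wins, ties broken by smaller tree size, then by random draw.
    """
    idx = rng.integers(0, len(population), size=size)
    best = np.min(fitness[idx])
    pool = [i for i in idx if fitness[i] == best]
    if len(pool) > 1:
        smallest = min(population[i].size() for i in pool)
        pool = [i for i in pool if population[i].size() == smallest]
    return int(pool[rng.integers(len(pool))]) if len(pool) > 1 else int(pool[0])


# ---------------------------------------------------------------------------
# The generational loop
# ---------------------------------------------------------------------------

def _evaluate_individual(tree: ex.Node, dataset: UptakeDataset,
                         config: GPConfig, rng: np.random.Generator,
                         cache: dict) -> tuple[ex.Node, float]:
    """Lamarckian refit + jackknife fitness; returns the updated genotype."""
    key = ex.serialize(tree)
    hit = cache.get(key)
    if hit is not None:
        return hit
    model = TreeModel(tree.copy())
    if model.n_params == 0 or dataset.n <= model.n_params:
        # unfittable or under-determined: score as-is / worst
        if model.n_params == 0:
            try:
                report = jackknife(model, dataset, objective=config.objective,
                                   restarts=0, rng=rng,
                                   max_nfev=config.max_nfev)
                out = (tree, report.mse_jk)
            except Exception:
                out = (tree, WORST_FITNESS)
        else:
            out = (tree, WORST_FITNESS)
        cache[key] = out
        return out
    try:
        res = fit(model, dataset, objective=config.objective,
                  restarts=config.fit_restarts, rng=rng,
                  max_nfev=config.max_nfev)
        if res.objective_value >= 1e19:
            # non-finite somewhere on the data: disqualify without paying
            # for N leave-one-out refits
            out = (tree, WORST_FITNESS)
        else:
            report = jackknife(model, dataset, objective=config.objective,
                               restarts=config.fit_restarts, rng=rng,
                               fit_result=res, max_nfev=config.max_nfev)
            updated = model.with_constants(res.beta_mse)
            out = (updated, report.mse_jk)
    except Exception:
        out = (tree, WORST_FITNESS)
    if not np.isfinite(out[1]):
        out = (out[0], WORST_FITNESS)
    cache[key] = out
    cache[ex.serialize(out[0])] = out
    return out


def evolve(dataset: UptakeDataset, config: GPConfig,
           seed: int | None = None) -> RunArchive:
    """One full GP run; bitwise reproducible under a fixed seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cache: dict = {}
    population = init_population(config, rng)
    archive = RunArchive(config=config, seed=seed)
    data = ArrayDataset.from_dataset(dataset)

    for gen in range(config.generations):
        evaluated = [_evaluate_individual(t, data, config, rng, cache)
                     for t in population]
        population = [t for t, _ in evaluated]
        fit_vals = np.array([f for _, f in evaluated])
        if not np.isfinite(fit_vals).any():
            raise DegenerateRunError(
                f"every candidate model non-finite at generation {gen}")
        order = np.lexsort((list(map(ex.Node.size, population)), fit_vals))
        best_i = int(order[0])
        archive.fitness_history.append(fit_vals)
        archive.best_per_gen.append(
            (ex.serialize(population[best_i]), float(fit_vals[best_i])))
        if fit_vals[best_i] < archive.best_fitness:
            archive.best_fitness = float(fit_vals[best_i])
            archive.best_tree = population[best_i].copy()
        if gen == config.generations - 1:
            break

        new_pop: list[ex.Node] = []
        if config.elitism:
            new_pop.append(population[best_i].copy())
        while len(new_pop) < config.population_size:
            r = rng.random()
            if r < config.p_crossover:
                i = tournament_select(population, fit_vals,
                                      config.tournament_size, rng)
                j = tournament_select(population, fit_vals,
                                      config.tournament_size, rng)
                c1, c2 = crossover(population[i], population[j], rng)
                for child, parent in ((c1, population[i]), (c2, population[j])):
                    if len(new_pop) >= config.population_size:
                        break
                    new_pop.append(child if child.depth() <= config.depth_limit
                                   else parent.copy())
            elif r < config.p_crossover + config.p_mutation:
                i = tournament_select(population, fit_vals,
                                      config.tournament_size, rng)
                child = mutate(population[i], rng, config)
                new_pop.append(child if child.depth() <= config.depth_limit
                               else population[i].copy())
            else:
                i = tournament_select(population, fit_vals,
                                      config.tournament_size, rng)
                new_pop.append(population[i].copy())
        population = new_pop

    archive.final_population = population
    return archive


def run_many(dataset: UptakeDataset, config: GPConfig,
             n_runs: int | None = None) -> list[RunArchive]:
    """Independent runs with seeds spawned deterministically from the config
    seed; the per-run best models form the curation candidate set."""
    n_runs = n_runs or config.n_runs
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             root.spawn(n_runs)]
    return [evolve(dataset, config, seed=s) for s in seeds]


# ---------------------------------------------------------------------------
# Population diagnostics
# ---------------------------------------------------------------------------

def variety(population: list[ex.Node]) -> float:
    """Fraction of structurally unique genotypes in the population."""
    if not population:
        raise ValueError("population must be non-empty")
    return len({ex.serialize(t) for t in population}) / len(population)


def median_fitness_trajectory(archive: RunArchive) -> np.ndarray:
    """Per-generation median fitness over finite values only."""
    out = []
    for gen_vals in archive.fitness_history:
        finite = gen_vals[np.isfinite(gen_vals)]
        out.append(float(np.median(finite)) if finite.size else np.nan)
    return np.array(out)


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------

class SymbolicRegressor(RegressorMixin, BaseEstimator):
    """Genetic-programming symbolic regression with jackknife fitness.

    ``X`` is ``(n_samples, 2)`` with columns ``(c0, t)``; ``y`` is the
    response in the units of the training table.  After ``fit`` the best
    genotype is in ``best_tree_`` / ``expression_`` and ``predict`` evaluates
    it.  All of :class:`GPConfig` is exposed as estimator parameters so the
    estimator composes with sklearn model selection.
    """

    def __init__(self, population_size=500, generations=50, p_crossover=0.9,
                 p_mutation=0.1, tournament_size=2, depth_limit=28,
                 init_depth_min=2, init_depth_max=6, mutation_max_depth=4,
                 objective="l2", fit_restarts=2, max_nfev=80, n_runs=1,
                 random_state=None):
        self.population_size = population_size
        self.generations = generations
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.tournament_size = tournament_size
        self.depth_limit = depth_limit
        self.init_depth_min = init_depth_min
        self.init_depth_max = init_depth_max
        self.mutation_max_depth = mutation_max_depth
        self.objective = objective
        self.fit_restarts = fit_restarts
        self.max_nfev = max_nfev
        self.n_runs = n_runs
        self.random_state = random_state

    def _config(self) -> GPConfig:
        return GPConfig(
            population_size=self.population_size,
            generations=self.generations, p_crossover=self.p_crossover,
            p_mutation=self.p_mutation, tournament_size=self.tournament_size,
            depth_limit=self.depth_limit, init_depth_min=self.init_depth_min,
            init_depth_max=self.init_depth_max,
            mutation_max_depth=self.mutation_max_depth,
            objective=self.objective, fit_restarts=self.fit_restarts,
            max_nfev=self.max_nfev, n_runs=self.n_runs,
            seed=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (c0, t)")
        frame = pd.DataFrame({"c0_uM": X[:, 0], "t_min": X[:, 1],
                              "value": y,
                              "replicate": np.ones(len(y), dtype=int)})
        dataset = UptakeDataset(frame, kind="uptake")
        config = self._config()
        if self.n_runs == 1:
            archives = [evolve(dataset, config, seed=self.random_state)]
        else:
            archives = run_many(dataset, config, self.n_runs)
        self.archives_ = archives
        best = min(archives, key=lambda a: a.best_fitness)
        self.archive_ = best
        self.best_tree_ = best.best_tree
        self.best_fitness_ = best.best_fitness
        self.expression_ = ex.serialize(best.best_tree)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return ex.evaluate(self.best_tree_, X[:, 0], X[:, 1])
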