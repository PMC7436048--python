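"""Binary PSO and genetic-algorithm feature selectors for fair comparison.

Both baselines share the grey-wolf driver's fitness function, data split and
evaluation budget (n_agents x n_iterations evaluations after the initial
population), and return the same :class:`~enosefs.argwo_driver.RunResult`.

BPSO follows the classical discrete binary particle swarm: continuous
velocities updated by inertia plus cognitive/social pulls toward personal and
global bests, clamped to +/-v_max, mapped through a sigmoid and compared to a
uniform draw per bit.  Inertia decays linearly 0.9 -> 0.4.

The GA uses tournament selection (size 2), uniform crossover, independent
per-bit mutation and elitism of one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .argwo_driver import RunResult, TraceRecord
from .fitness import DataSplit, FitnessWeights, evaluate_subset


@dataclass(frozen=True)
class BpsoConfig:
    c1: float = 2.0
    c2: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    v_max: float = 6.0
    n_particles: int = 40
    n_iterations: int = 30

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0 or self.v_max <= 0:
            raise ValueError("c1, c2 and v_max must be positive")


@dataclass(frozen=True)
class GaConfig:
    mutation_rate: float = 0.02
    crossover_rate: float = 0.8
    population: int = 40
    generations: int = 30
    elitism: int = 1
    tournament_size: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


class _Archive:
    """Best-ever (fitness, mask) tracker shared by both baselines."""

    def __init__(self, dim: int):
        self.fit = np.inf
        self.mask = np.zeros(dim, dtype=np.int8)
        self.n_evals = 0

    def evaluate(self, masks, split, weights, k=5) -> np.ndarray:
        fits = np.empty(masks.shape[0])
        for i in range(masks.shape[0]):
            res = evaluate_subset(masks[i], split, weights, k)
            fits[i] = res.fitness
            self.n_evals += 1
            if res.fitness < self.fit:
                self.fit = res.fitness
                self.mask = masks[i].copy()
        return fits


def bpso_run(
    config: BpsoConfig,
    split: DataSplit,
    weights: FitnessWeights = FitnessWeights(),
    seed: int = 0,
    k_neighbors: int = 5,
) -> RunResult:
    """Discrete binary particle swarm optimization over feature masks."""
    rng = np.random.default_rng(seed)
    n, dim = config.n_particles, split.n_features
    arch = _Archive(dim)

    x = (rng.random((n, dim)) >= 0.5).astype(np.int8)
    v = rng.uniform(-config.v_max, config.v_max, (n, dim))
    fits = arch.evaluate(x, split, weights, k_neighbors)
    pbest_x, pbest_f = x.copy(), fits.copy()
    g = int(pbest_f.argmin())
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    trace = [TraceRecord(0, float(fits.min()), arch.fit, 0)]

    for t in range(config.n_iterations):
        w = config.inertia_start + (config.inertia_end - config.inertia_start) * (
            t / max(config.n_iterations - 1, 1)
        )
        r1, r2 = rng.random((n, dim)), rng.random((n, dim))
        v = w * v + config.c1 * r1 * (pbest_x - x) + config.c2 * r2 * (gbest_x[None, :] - x)
        np.clip(v, -config.v_max, config.v_max, out=v)
        s = 1.0 / (1.0 + np.exp(-v))
        x = (s >= rng.random((n, dim))).astype(np.int8)

        fits = arch.evaluate(x, split, weights, k_neighbors)
        improved = fits < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fits[improved]
        g = int(pbest_f.argmin())
        if pbest_f[g] < gbest_f:
            gbest_f, gbest_x = float(pbest_f[g]), pbest_x[g].copy()
        trace.append(TraceRecord(t + 1, float(fits.min()), arch.fit, 0))

    return RunResult(arch.mask, float(arch.fit), trace, seed, arch.n_evals, config)


def ga_run(
    config: GaConfig,
    split: DataSplit,
    weights: FitnessWeights = FitnessWeights(),
    seed: int = 0,
    k_neighbors: int = 5,
    initial_population: np.ndarray | None = None,
) -> RunResult:
    """Genetic-algorithm bitstring feature selection.

    ``initial_population`` overrides the random initial bitstrings (shape
    (population, n_features)); useful for controlled studies of the variation
    operators.
    """
    rng = np.random.default_rng(seed)
    n, dim = config.population, split.n_features
    arch = _Archive(dim)

    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=np.int8).copy()
        if pop.shape != (n, dim):
            raise ValueError("initial_population must have shape (population, n_features)")
    else:
        pop = (rng.random((n, dim)) >= 0.5).astype(np.int8)
    fits = arch.evaluate(pop, split, weights, k_neighbors)
    trace = [TraceRecord(0, float(fits.min()), arch.fit, 0)]

    for t in range(config.generations):
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < n:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, n, size=config.tournament_size)
                parents.append(pop[contenders[np.argmin(fits[contenders])]])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(dim) < 0.5
                c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
            for child in (c1, c2):
                flip = rng.random(dim) < config.mutation_rate
                child[flip] ^= 1
                if len(new_pop) < n:
                    new_pop.append(child)
        pop = np.array(new_pop, dtype=np.int8)
        fits = arch.evaluate(pop, split, weights, k_neighbors)
        trace.append(TraceRecord(t + 1, float(fits.min()), arch.fit, 0))

    return RunResult(arch.mask, float(arch.fit), trace, seed, arch.n_evals, config)
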