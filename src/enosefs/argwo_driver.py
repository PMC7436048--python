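"""Adaptive-restart grey wolf feature selection driver.

One run: initialize a pack of agents with continuous positions i.i.d. U(0,1)
(iteration-0 masks by thresholding at 0.5), evaluate, then iterate for a fixed
budget: leader-guided continuous update, binarization, fitness evaluation, the
adaptive restart check, and the leader refresh.

Adaptive restart: when the iteration-best fitness f_t fails to improve on the
previous iteration (f_t >= f_{t-1}), round(Ns * f_t) agents chosen uniformly
at random — leaders included — have their continuous positions re-drawn
U(0,1).  The worse the stagnating fitness, the larger the restarted slice.
Restarted agents are re-evaluated at the next iteration's evaluation pass; the
leader refresh that follows a restart therefore reads last-known fitnesses.

A global best-ever archive tracks the minimum fitness over every evaluation,
so the returned solution never regresses even if a restart wipes the alpha.

Five GWO variants share this loop: ``bgwo`` (sigmoid transfer, no restart),
``gwo1``/``gwo2`` (leader-vote / min-max transfer, no restart) and
``argwo1``/``argwo2`` (the same transfers with adaptive restart).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binary_transforms import approach1_binarize, approach2_binarize, sigmoid_binarize
from .fitness import DataSplit, FitnessWeights, evaluate_subset
from .gwo_core import (
    PackState,
    SearchConfig,
    draw_coefficients,
    leader_guided_update,
    linear_schedule,
    update_leaders,
)

TRANSFORMS = ("sigmoid", "approach1", "approach2")

#: algorithm name -> (transform, restart_enabled)
GWO_VARIANTS = {
    "bgwo": ("sigmoid", False),
    "gwo1": ("approach1", False),
    "gwo2": ("approach2", False),
    "argwo1": ("approach1", True),
    "argwo2": ("approach2", True),
}


@dataclass(frozen=True)
class RunConfig:
    search: SearchConfig
    transform: str = "approach2"
    restart_enabled: bool = True
    weights: FitnessWeights = FitnessWeights()
    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}; choose from {TRANSFORMS}")


@dataclass
class TraceRecord:
    iteration: int
    iter_best: float
    best_ever: float
    n_restarted: int


@dataclass
class RunResult:
    """Best-ever mask and fitness with the full per-iteration trace."""

    best_mask: np.ndarray
    best_fitness: float
    trace: list[TraceRecord]
    seed: int
    n_evaluations: int
    config_echo: object = None

    def trace_dicts(self) -> list[dict]:
        return [vars(r).copy() for r in self.trace]


def restart_count(f_t: float, n_agents: int) -> int:
    """Number of agents to re-initialize: round(Ns * f_t), half away from zero."""
    if not 0.0 <= f_t <= 1.0:
        raise ValueError("fitness must lie in [0, 1]")
    return int(math.floor(n_agents * f_t + 0.5))


def maybe_restart(
    pack: PackState, f_prev: float, f_curr: float, rng: np.random.Generator
) -> tuple[PackState, int]:
    """Re-draw positions of round(Ns*f_curr) random agents when fitness stagnates.

    Triggers iff f_curr >= f_prev.  Restarted agents keep their last-known
    fitness and mask until the next evaluation pass (stale by design); the
    pack is returned unchanged otherwise.
    """
    if f_curr < f_prev:
        return pack, 0
    n_r = restart_count(f_curr, pack.n_agents)
    if n_r > 0:
        idx = rng.choice(pack.n_agents, size=n_r, replace=False)
        pack.positions[idx] = rng.random((n_r, pack.dimension))
    return pack, n_r


def run(config: RunConfig, split: DataSplit) -> RunResult:
    """Execute one seeded feature-selection run; fully reproducible from its inputs."""
    search = config.search
    if search.dimension != split.n_features:
        raise ValueError(
            f"search dimension {search.dimension} != table width {split.n_features}"
        )
    rng = np.random.default_rng(search.seed)
    n, dim = search.n_agents, search.dimension

    positions = rng.random((n, dim))
    masks = (positions >= 0.5).astype(np.int8)
    n_evals = 0

    best_fit = np.inf
    best_mask = masks[0].copy()

    def evaluate_all(pack_masks: np.ndarray) -> np.ndarray:
        nonlocal n_evals, best_fit, best_mask
        fits = np.empty(pack_masks.shape[0])
        for i in range(pack_masks.shape[0]):
            res = evaluate_subset(pack_masks[i], split, config.weights, config.k_neighbors)
            fits[i] = res.fitness
            n_evals += 1
            if res.fitness < best_fit:
                best_fit = res.fitness
                best_mask = pack_masks[i].copy()
        return fits

    fitnesses = evaluate_all(masks)
    pack = PackState(positions=positions, masks=masks, fitnesses=fitnesses)
    update_leaders(pack)
    f_prev = float(fitnesses.min())
    trace = [TraceRecord(0, f_prev, float(best_fit), 0)]

    for t in range(search.n_iterations):
        a = linear_schedule(t, search.n_iterations)
        new_positions = np.empty_like(pack.positions)
        for i in range(n):
            coeffs = draw_coefficients(a, dim, rng)
            new_positions[i] = leader_guided_update(pack.positions[i], pack.leaders, coeffs)
            if config.transform == "approach1":
                pack.masks[i], _ = approach1_binarize(pack.leaders, coeffs, rng)
            elif config.transform == "approach2":
                pack.masks[i] = approach2_binarize(new_positions[i], rng)
            else:
                pack.masks[i] = sigmoid_binarize(new_positions[i], rng)
        pack.positions = new_positions
        pack.fitnesses = evaluate_all(pack.masks)
        f_curr = float(pack.fitnesses.min())

        n_restarted = 0
        if config.restart_enabled:
            pack, n_restarted = maybe_restart(pack, f_prev, f_curr, rng)
        update_leaders(pack)
        pack.iteration = t + 1
        f_prev = f_curr
        trace.append(TraceRecord(t + 1, f_curr, float(best_fit), n_restarted))

    return RunResult(
        best_mask=best_mask,
        best_fitness=float(best_fit),
        trace=trace,
        seed=search.seed,
        n_evaluations=n_evals,
        config_echo=config,
    )


def run_variant(
    algorithm: str,
    split: DataSplit,
    seed: int = 0,
    n_agents: int = 40,
    n_iterations: int = 30,
    weights: FitnessWeights = FitnessWeights(),
    k_neighbors: int = 5,
) -> RunResult:
    """Run one named GWO variant (bgwo, gwo1, gwo2, argwo1, argwo2)."""
    if algorithm not in GWO_VARIANTS:
        raise ValueError(f"unknown GWO variant {algorithm!r}; choose from {sorted(GWO_VARIANTS)}")
    transform, restart = GWO_VARIANTS[algorithm]
    cfg = RunConfig(
        search=SearchConfig(n_agents, n_iterations, split.n_features, seed),
        transform=transform,
        restart_enabled=restart,
        weights=weights,
        k_neighbors=k_neighbors,
    )
    return run(cfg, split)
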