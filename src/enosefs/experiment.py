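"""Reproducible multi-run experiment orchestration.

An experiment runs each requested selector ``n_repeats`` times with seeds
``base_seed + i`` on one shared data split, then summarizes: run-set fitness
statistics, the optimal run per algorithm (the paper-style rule: fewest
selected features among the runs attaining the maximal k-NN test accuracy),
per-classifier scores of that optimal mask, and a pairwise Wilcoxon p-value
matrix over the per-run final fitnesses.  The report is a plain
JSON-serializable dict embedding the resolved configuration and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .argwo_driver import GWO_VARIANTS, RunResult, run_variant
from .baselines import BpsoConfig, GaConfig, bpso_run, ga_run
from .fitness import DataSplit, FitnessWeights, evaluate_subset
from .metrics import run_set_stats, score_subset_with_classifiers, wilcoxon_compare

ALL_ALGORITHMS = tuple(sorted(GWO_VARIANTS)) + ("bpso", "ga")


@dataclass(frozen=True)
class ExperimentSpec:
    algorithms: tuple[str, ...] = ("argwo2", "bgwo")
    n_repeats: int = 20
    base_seed: int = 0
    n_agents: int = 40
    n_iterations: int = 30
    k_neighbors: int = 5
    weights: FitnessWeights = field(default_factory=FitnessWeights)

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("need at least one algorithm")
        unknown = set(self.algorithms) - set(ALL_ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}; choose from {ALL_ALGORITHMS}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def run_algorithm(algorithm: str, split: DataSplit, seed: int, spec: ExperimentSpec) -> RunResult:
    """Run one selector once; every selector shares fitness, split and budget."""
    if algorithm in GWO_VARIANTS:
        return run_variant(
            algorithm, split, seed=seed,
            n_agents=spec.n_agents, n_iterations=spec.n_iterations,
            weights=spec.weights, k_neighbors=spec.k_neighbors,
        )
    if algorithm == "bpso":
        cfg = BpsoConfig(n_particles=spec.n_agents, n_iterations=spec.n_iterations)
        return bpso_run(cfg, split, spec.weights, seed=seed, k_neighbors=spec.k_neighbors)
    if algorithm == "ga":
        cfg = GaConfig(population=spec.n_agents, generations=spec.n_iterations)
        return ga_run(cfg, split, spec.weights, seed=seed, k_neighbors=spec.k_neighbors)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def select_optimal_run(results: list[RunResult], split: DataSplit, spec: ExperimentSpec):
    """Paper-style optimal result: max k-NN test accuracy, ties -> fewest features."""
    scored = []
    for r in results:
        res = evaluate_subset(r.best_mask, split, spec.weights, spec.k_neighbors)
        scored.append((1.0 - res.error_rate, -res.n_selected, r))
    scored.sort(key=lambda s: (s[0], s[1]), reverse=True)
    return scored[0][2]


def run_experiment(spec: ExperimentSpec, split: DataSplit, with_traces: bool = False) -> dict:
    """Run the full comparison; returns a JSON-serializable report."""
    per_algo: dict[str, dict] = {}
    finals: dict[str, np.ndarray] = {}
    for algo in spec.algorithms:
        results = [
            run_algorithm(algo, split, spec.base_seed + i, spec)
            for i in range(spec.n_repeats)
        ]
        fits = np.array([r.best_fitness for r in results])
        finals[algo] = fits
        stats = run_set_stats(fits)
        opt = select_optimal_run(results, split, spec)
        opt_eval = evaluate_subset(opt.best_mask, split, spec.weights, spec.k_neighbors)
        entry = {
            "final_fitnesses": fits.tolist(),
            "stats": vars(stats),
            "optimal": {
                "seed": opt.seed,
                "best_fitness": opt.best_fitness,
                "n_selected": opt_eval.n_selected,
                "mask": opt.best_mask.tolist(),
                "scores": score_subset_with_classifiers(opt.best_mask, split, k=spec.k_neighbors),
            },
        }
        if with_traces:
            entry["traces"] = [r.trace_dicts() for r in results]
        per_algo[algo] = entry

    pvals: dict[str, dict[str, float]] = {}
    if spec.n_repeats >= 5:
        for a in spec.algorithms:
            pvals[a] = {}
            for b in spec.algorithms:
                if a != b:
                    pvals[a][b] = wilcoxon_compare(finals[a], finals[b])

    return {
        "config": {
            "algorithms": list(spec.algorithms),
            "n_repeats": spec.n_repeats,
            "base_seed": spec.base_seed,
            "n_agents": spec.n_agents,
            "n_iterations": spec.n_iterations,
            "k_neighbors": spec.k_neighbors,
            "accuracy_weight": spec.weights.accuracy_weight,
            "split_seed": split.split_seed,
            "split_fraction": split.split_fraction,
            "n_features": split.n_features,
        },
        "algorithms": per_algo,
        "wilcoxon_p": pvals,
    }
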