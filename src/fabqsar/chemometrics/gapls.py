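"""GA-PLS consensus descriptor selection.

A binary-chromosome genetic algorithm (gene = descriptor inclusion)
whose fitness is the cross-validated RMSE of a PLS1 model on the
calibration set, with the latent-variable count chosen by the same CV.
A single GA run is prone to overfitting a particular descriptor
combination, so the search is repeated (10 seeded runs by default) and
the consensus subset keeps descriptors selected in at least half of the
runs' best chromosomes.

GA operators: initial population includes each descriptor with
probability 0.30; parents picked by binary tournament; double (two-point)
crossover; per-gene mutation rate 0.005; elitism of the best chromosome;
a run terminates at the generation cap or when at least half of the
population shares the best fitness (convergence 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import cv_rmse_pls, make_cv_folds


@dataclass
class GaPlsConfig:
    population_size: int = 64
    max_generations: int = 100
    mutation_rate: float = 0.005
    window_width: int = 1       # carried for config fidelity; 1 = per-descriptor genes
    convergence: float = 0.5
    initial_terms_fraction: float = 0.30
    crossover: int = 2          # double crossover
    n_runs: int = 10
    consensus_threshold: float = 0.5
    max_latent_variables: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.convergence <= 1:
            raise ValueError("convergence in (0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate in [0, 1]")
        if self.crossover not in (1, 2):
            raise ValueError("crossover must be single (1) or double (2)")


@dataclass
class RunReport:
    seed: int
    best_chromosome: np.ndarray
    best_fitness: float
    generations: int


@dataclass
class GaPlsResult:
    consensus: list[str]
    runs: list[RunReport]
    counts: dict[str, int] = field(default_factory=dict)


def _evaluate(chrom: np.ndarray, x: np.ndarray, y: np.ndarray,
              config: GaPlsConfig, folds: list[np.ndarray],
              cache: dict[bytes, float]) -> float:
    key = chrom.tobytes()
    if key in cache:
        return cache[key]
    cols = np.where(chrom)[0]
    if len(cols) == 0:
        fit = np.inf
    else:
        fit, _ = cv_rmse_pls(x[:, cols], y, config.max_latent_variables,
                             folds=folds)
    cache[key] = fit
    return fit


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
               n_points: int) -> tuple[np.ndarray, np.ndarray]:
    p = len(a)
    if p < 2:
        return a.copy(), b.copy()
    cuts = np.sort(rng.choice(np.arange(1, p), size=min(n_points, p - 1),
                              replace=False))
    c1, c2 = a.copy(), b.copy()
    swap = False
    prev = 0
    for cut in list(cuts) + [p]:
        if swap:
            c1[prev:cut], c2[prev:cut] = b[prev:cut].copy(), a[prev:cut].copy()
        swap = not swap
        prev = cut
    return c1, c2


def _single_run(x: np.ndarray, y: np.ndarray, names: list[str],
                config: GaPlsConfig, seed: int) -> RunReport:
    rng = np.random.default_rng(seed)
    p = x.shape[1]
    pop = rng.random((config.population_size, p)) < config.initial_terms_fraction
    # guarantee non-empty chromosomes
    for i in range(config.population_size):
        if not pop[i].any():
            pop[i, rng.integers(p)] = True
    cache: dict[bytes, float] = {}
    # fold assignment fixed per run so fitnesses are comparable
    folds = make_cv_folds(len(y), config.cv_folds, seed)
    fitness = np.array([_evaluate(c, x, y, config, folds, cache)
                        for c in pop])

    gen = 0
    for gen in range(1, config.max_generations + 1):
        best_fit = fitness.min()
        share = (np.isclose(fitness, best_fit, rtol=1e-12, atol=1e-12)).mean()
        if share >= config.convergence:
            break
        order = np.argsort(fitness, kind="stable")
        elite = pop[order[0]].copy()
        children = [elite]
        while len(children) < config.population_size:
            # binary tournaments
            picks = rng.integers(config.population_size, size=4)
            pa = pop[picks[0]] if fitness[picks[0]] <= fitness[picks[1]] else pop[picks[1]]
            pb = pop[picks[2]] if fitness[picks[2]] <= fitness[picks[3]] else pop[picks[3]]
            c1, c2 = _crossover(pa, pb, rng, config.crossover)
            for c in (c1, c2):
                mut = rng.random(p) < config.mutation_rate
                c ^= mut
                if not c.any():
                    c[rng.integers(p)] = True
                children.append(c)
        pop = np.array(children[: config.population_size])
        fitness = np.array([_evaluate(c, x, y, config, folds, cache)
                            for c in pop])

    best_idx = int(np.argmin(fitness))
    return RunReport(seed=seed, best_chromosome=pop[best_idx].copy(),
                     best_fitness=float(fitness[best_idx]), generations=gen)


def ga_pls_select(calibration: pd.DataFrame, y: pd.Series | np.ndarray,
                  config: GaPlsConfig | None = None) -> GaPlsResult:
    """Run the seeded GA n_runs times and build the consensus subset.

    ``calibration`` must be the autoscaled calibration descriptor matrix;
    the consensus keeps descriptors present in at least
    ceil(consensus_threshold * n_runs) of the runs' best chromosomes.
    Runs are ranked by best CV RMSE in the per-run report.
    """
    config = config or GaPlsConfig()
    names = list(calibration.columns)
    x = calibration.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    if len(names) == 1:
        chrom = np.array([True])
        runs = [RunReport(seed=config.seed, best_chromosome=chrom,
                          best_fitness=float(
                              cv_rmse_pls(x, y, 1, config.cv_folds,
                                          config.seed)[0]),
                          generations=0)]
        return GaPlsResult(consensus=names, runs=runs, counts={names[0]: 1})

    runs = [_single_run(x, y, names, config, config.seed + r)
            for r in range(config.n_runs)]
    runs.sort(key=lambda r: r.best_fitness)

    votes = np.sum([r.best_chromosome for r in runs], axis=0)
    needed = math.ceil(config.consensus_threshold * config.n_runs)
    consensus = [names[j] for j in range(len(names)) if votes[j] >= needed]
    if not consensus:
        # degenerate fallback: take the best run's chromosome
        consensus = [names[j] for j in np.where(runs[0].best_chromosome)[0]]
    counts = {names[j]: int(votes[j]) for j in range(len(names)) if votes[j]}
    return GaPlsResult(consensus=consensus, runs=runs, counts=counts)
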