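"""Search engines driving the grammatical evolution: a GA and DE/Rand/1.

Both engines minimise an arbitrary fitness callback ``fitness_fn(codons) ->
float`` over fixed-length codon genotypes under a hard budget of fitness
evaluations.  The GA works on a bit-string genome grouped MSB-first into
8-bit codons; DE works directly on a real vector in [0, 255]^D whose
components are floored to integer codons at evaluation time.

Randomness: each search owns a single seeded generator.  The stream order is
initialisation first, then per generation selection / crossover / mutation in
population order, so identical seeds reproduce a run bit for bit.

Budget accounting: every newly created individual costs exactly one fitness
call; cached fitnesses (GA elites, DE survivors) are never re-evaluated.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .grammar import Genotype

__all__ = [
    "GAConfig",
    "DEConfig",
    "SearchResult",
    "ga_search",
    "de_search",
    "tournament_select",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class GAConfig:
    """Generational GA over bit-string genomes.

    Defaults follow the study protocol: 8 bits per codon, 4000-bit genomes
    (500 codons), population 100, 5-tournament selection, 10% elitism,
    one-point crossover and independent per-bit negation with probability
    0.05.
    """

    bits_per_codon: int = 8
    genome_bits: int = 4000
    population: int = 100
    budget: int = 1_000_000
    tournament_k: int = 5
    elitism_fraction: float = 0.10
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_bits % self.bits_per_codon != 0:
            raise ValueError("genome_bits must be divisible by bits_per_codon")
        if not (0 <= self.elitism_fraction < 1):
            raise ValueError("elitism_fraction must lie in [0, 1)")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.tournament_k < 1:
            raise ValueError("tournament_k must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")

    @property
    def n_codons(self) -> int:
        return self.genome_bits // self.bits_per_codon


@dataclass(frozen=True)
class DEConfig:
    """DE/Rand/1/bin over real vectors in [0, 255]^dimension.

    The differential weight F is not part of the study's stated parameters;
    the conventional 0.5 is the default and it is exposed here.
    """

    dimension: int = 500
    domain: tuple[float, float] = (0.0, 255.0)
    population: int = 100
    budget: int = 1_000_000
    crossover_rate: float = 0.10
    F: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.crossover_rate <= 1):
            raise ValueError("crossover_rate must lie in (0, 1]")
        if self.F <= 0:
            raise ValueError("F must be positive")
        if self.domain[0] >= self.domain[1]:
            raise ValueError("domain lower bound must be below upper bound")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one search run."""

    best_genotype: Genotype
    best_fitness: float
    history: tuple[float, ...]  # best-so-far fitness after each generation
    evaluations_used: int


def tournament_select(fitnesses: np.ndarray, k: int, rng: np.random.Generator) -> int:
    """Index of the minimum-fitness member among k uniform draws (with replacement)."""
    if len(fitnesses) == 0:
        raise ValueError("empty population")
    if k < 1:
        raise ValueError("k must be >= 1")
    draws = rng.integers(0, len(fitnesses), size=k)
    return int(draws[np.argmin(np.asarray(fitnesses)[draws])])


def bits_to_codons(bits: np.ndarray, bits_per_codon: int = 8) -> np.ndarray:
    """Group a bit vector MSB-first into integer codons."""
    weights = 2 ** np.arange(bits_per_codon - 1, -1, -1)
    return bits.reshape(-1, bits_per_codon) @ weights


class _ProgressLog:
    def __init__(self, path: Optional[Union[str, Path]]):
        self._rows: list[tuple[int, int, float, float]] = []
        self._path = Path(path) if path is not None else None

    def record(self, generation: int, evals: int, best: float, mean: float) -> None:
        self._rows.append((generation, evals, best, mean))

    def flush(self) -> None:
        if self._path is None:
            return
        with open(self._path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["generation", "evaluations", "best_fitness", "mean_fitness"])
            writer.writerows(self._rows)


def ga_search(
    fitness_fn: FitnessFn,
    cfg: GAConfig,
    log_path: Optional[Union[str, Path]] = None,
) -> SearchResult:
    """Generational GA with elitism, tournament selection, one-point crossover.

    Per generation: the top ``ceil(elitism * population)`` individuals are
    copied unchanged (fitness cached); the remainder are children of two
    tournament winners combined by one-point crossover and mutated bit-wise.
    Stops when the evaluation budget is exhausted; a final partial generation
    is topped up with the best survivors so population size is conserved.
    """
    if cfg.budget < cfg.population:
        raise ValueError("budget must cover at least the initial population")
    rng = np.random.default_rng(cfg.seed)
    log = _ProgressLog(log_path)

    pop = rng.integers(0, 2, size=(cfg.population, cfg.genome_bits), dtype=np.int8)
    fit = np.array(
        [fitness_fn(bits_to_codons(ind, cfg.bits_per_codon)) for ind in pop]
    )
    evals = cfg.population
    n_elite = math.ceil(cfg.elitism_fraction * cfg.population)

    best_idx = int(np.argmin(fit))
    best_bits = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]
    generation = 0
    log.record(generation, evals, best_fit, float(fit.mean()))

    while evals < cfg.budget:
        generation += 1
        order = np.argsort(fit, kind="stable")
        n_children = min(cfg.population - n_elite, cfg.budget - evals)
        children = np.empty((n_children, cfg.genome_bits), dtype=np.int8)
        child_fit = np.empty(n_children)
        for c in range(n_children):
            p1 = pop[tournament_select(fit, cfg.tournament_k, rng)]
            p2 = pop[tournament_select(fit, cfg.tournament_k, rng)]
            cut = int(rng.integers(1, cfg.genome_bits))
            child = np.concatenate([p1[:cut], p2[cut:]])
            flips = rng.random(cfg.genome_bits) < cfg.mutation_rate
            child = np.where(flips, 1 - child, child).astype(np.int8)
            children[c] = child
            child_fit[c] = fitness_fn(bits_to_codons(child, cfg.bits_per_codon))
        evals += n_children
        # survivors fill any shortfall left by a budget-truncated generation
        n_keep = cfg.population - n_children
        keep = order[:n_keep]
        pop = np.vstack([pop[keep], children])
        fit = np.concatenate([fit[keep], child_fit])

        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_bits = pop[gen_best].copy()
        history.append(best_fit)
        log.record(generation, evals, best_fit, float(fit.mean()))

    log.flush()
    codons = bits_to_codons(best_bits, cfg.bits_per_codon)
    return SearchResult(
        best_genotype=Genotype(tuple(int(c) for c in codons), "binary-derived"),
        best_fitness=best_fit,
        history=tuple(history),
        evaluations_used=evals,
    )


def _floor_codons(x: np.ndarray, upper: float) -> np.ndarray:
    return np.minimum(np.floor(x), math.floor(upper)).astype(int)


def de_search(
    fitness_fn: FitnessFn,
    cfg: DEConfig,
    log_path: Optional[Union[str, Path]] = None,
) -> SearchResult:
    """DE/Rand/1 with binomial crossover and greedy selection.

    For each target x_i a mutant v = x_r1 + F (x_r2 - x_r3) is built from
    three distinct random members (all different from i), crossed over
    component-wise with probability CR (one component guaranteed), clamped
    into the domain, and accepted when its fitness is better *or equal* —
    ties move to the trial, which lets the population drift across the
    plateaus created by the accuracy-error fitness.
    """
    if cfg.population < 4:
        raise ValueError("DE needs a population of at least 4")
    if cfg.budget < cfg.population:
        raise ValueError("budget must cover at least the initial population")
    rng = np.random.default_rng(cfg.seed)
    log = _ProgressLog(log_path)
    lo, hi = cfg.domain

    pop = rng.uniform(lo, hi, size=(cfg.population, cfg.dimension))
    fit = np.array([fitness_fn(_floor_codons(ind, hi)) for ind in pop])
    evals = cfg.population

    best_idx = int(np.argmin(fit))
    best_vec = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]
    generation = 0
    log.record(generation, evals, best_fit, float(fit.mean()))

    while evals < cfg.budget:
        generation += 1
        for i in range(cfg.population):
            if evals >= cfg.budget:
                break
            r = rng.choice(cfg.population - 1, size=3, replace=False)
            r1, r2, r3 = (int(j) if j < i else int(j) + 1 for j in r)
            mutant = pop[r1] + cfg.F * (pop[r2] - pop[r3])
            np.clip(mutant, lo, hi, out=mutant)
            jrand = int(rng.integers(cfg.dimension))
            mask = rng.random(cfg.dimension) < cfg.crossover_rate
            mask[jrand] = True
            trial = np.where(mask, mutant, pop[i])
            trial_fit = float(fitness_fn(_floor_codons(trial, hi)))
            evals += 1
            if trial_fit <= fit[i]:
                pop[i] = trial
                fit[i] = trial_fit
                if trial_fit < best_fit:
                    best_fit = trial_fit
                    best_vec = trial.copy()
        history.append(best_fit)
        log.record(generation, evals, best_fit, float(fit.mean()))

    log.flush()
    codons = _floor_codons(best_vec, hi)
    return SearchResult(
        best_genotype=Genotype(tuple(int(c) for c in codons), "real-derived"),
        best_fitness=best_fit,
        history=tuple(history),
        evaluations_used=evals,
    )
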