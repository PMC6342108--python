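"""A small real-coded genetic algorithm with categorical genes.

Tournament selection, blend (BLX-alpha) crossover on continuous genes,
Gaussian mutation, uniform resampling on categorical genes, elitism of one,
and a stagnation-based stop.  Fitness is maximized.  The best fitness per
generation is logged so convergence can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaConfig", "GeneSpec", "GeneticAlgorithm"]


@dataclass
class GeneSpec:
    """One gene: continuous in [lo, hi] (log-scaled if log=True) or
    categorical over ``choices``."""

    kind: str  # "continuous" | "categorical"
    lo: float = 0.0
    hi: float = 1.0
    log: bool = False
    choices: tuple = ()

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        return float(rng.uniform(self.lo, self.hi))

    def clip(self, v: float) -> float:
        return float(min(max(v, self.lo), self.hi))


@dataclass
class GaConfig:
    """Genetic-algorithm settings (population >= 10)."""

    population: int = 40
    max_generations: int = 100
    stagnation: int = 15
    seed: int = 0
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.25
    mutation_scale: float = 0.15  # sd as a fraction of the gene span
    elitism: int = 1

    def __post_init__(self) -> None:
        if self.population < 10:
            raise ValueError("population must be at least 10")
        if self.stagnation < 1 or self.max_generations < 1:
            raise ValueError("generation limits must be positive")


@dataclass
class GaResult:
    best: list
    best_fitness: float
    history: list[float] = field(default_factory=list)
    n_generations: int = 0


class GeneticAlgorithm:
    """Maximize ``fitness(chromosome)`` over mixed gene spaces."""

    def __init__(self, genes: list[GeneSpec], fitness, config: GaConfig):
        self.genes = genes
        self.fitness = fitness
        self.config = config

    def _random_individual(self, rng) -> list:
        return [g.sample(rng) for g in self.genes]

    def _crossover(self, a: list, b: list, rng) -> list:
        child = []
        for g, va, vb in zip(self.genes, a, b):
            if g.kind == "categorical":
                child.append(va if rng.random() < 0.5 else vb)
            else:
                # BLX-0.5 blend
                lo, hi = min(va, vb), max(va, vb)
                span = hi - lo
                child.append(g.clip(rng.uniform(lo - 0.5 * span, hi + 0.5 * span)))
        return child

    def _mutate(self, ind: list, rng) -> list:
        out = list(ind)
        for k, g in enumerate(self.genes):
            if rng.random() >= self.config.mutation_rate:
                continue
            if g.kind == "categorical":
                out[k] = g.choices[rng.integers(len(g.choices))]
            elif g.log:
                log_span = np.log(g.hi) - np.log(g.lo)
                v = np.log(out[k]) + rng.normal(0, self.config.mutation_scale * log_span)
                out[k] = g.clip(float(np.exp(v)))
            else:
                span = g.hi - g.lo
                out[k] = g.clip(out[k] + rng.normal(0, self.config.mutation_scale * span))
        return out

    def run(self) -> GaResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        pop = [self._random_individual(rng) for _ in range(cfg.population)]
        fit = np.array([self.fitness(ind) for ind in pop])
        history: list[float] = []
        best_idx = int(np.argmax(fit))
        best, best_fit = list(pop[best_idx]), float(fit[best_idx])
        stall = 0
        gen = 0
        for gen in range(1, cfg.max_generations + 1):
            new_pop = [list(best)]  # elitism of 1
            while len(new_pop) < cfg.population:
                cand = rng.integers(0, cfg.population, size=cfg.tournament)
                pa = pop[cand[np.argmax(fit[cand])]]
                cand = rng.integers(0, cfg.population, size=cfg.tournament)
                pb = pop[cand[np.argmax(fit[cand])]]
                child = (
                    self._crossover(pa, pb, rng)
                    if rng.random() < cfg.crossover_rate
                    else list(pa)
                )
                new_pop.append(self._mutate(child, rng))
            pop = new_pop
            fit = np.array([self.fitness(ind) for ind in pop])
            gen_best = int(np.argmax(fit))
            if fit[gen_best] > best_fit + 1e-12:
                best, best_fit = list(pop[gen_best]), float(fit[gen_best])
                stall = 0
            else:
                stall += 1
            history.append(best_fit)
            if stall >= cfg.stagnation:
                break
        return GaResult(best=best, best_fitness=best_fit, history=history,
                        n_generations=gen)
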