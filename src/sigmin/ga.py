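"""Genetic-algorithm optimisation of fixed-size signatures.

Individuals are fixed-size probeset sets; fitness is 1-NN prediction
accuracy.  Generations keep the top elite fraction unchanged (so the best
fitness can never decrease) and refill the remainder with offspring:
with probability ``crossover_rate`` a uniform size-preserving sample from
the union of two distinct elites, otherwise a single-element replacement
mutation of one elite.  Both operators preserve signature size and
uniqueness by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import TargetAnnotationTable
from .expr_data import ExpressionMatrix
from .prediction import PredictionConfig, predict_and_score
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "GenerationStats", "GATrace", "evolve", "crossover", "mutate"]


@dataclass(frozen=True)
class GAConfig:
    """Knobs of the evolutionary search (defaults mirror the full-scale study)."""

    signature_size: int
    population: int = 200
    generations: int = 150
    elite_fraction: float = 0.20
    crossover_rate: float = 0.70
    mutation_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.crossover_rate + self.mutation_rate - 1.0) > 1e-12:
            raise ValueError("crossover_rate + mutation_rate must equal 1")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")

    @property
    def n_elite(self) -> int:
        return math.ceil(self.elite_fraction * self.population)


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    best: float
    mean: float
    worst: float
    distinct_probesets: int  # population diversity: distinct ids across all individuals


@dataclass(frozen=True)
class GATrace:
    generations: tuple[GenerationStats, ...]
    best_signature: GeneSignature
    best_fitness: float

    @property
    def best_per_generation(self) -> list[float]:
        return [g.best for g in self.generations]


def _rng_from(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def crossover(a: GeneSignature, b: GeneSignature, seed: int | np.random.Generator) -> GeneSignature:
    """Child = uniform sample of size |a| without replacement from a ∪ b."""
    if a.size != b.size:
        raise ValueError(f"parent sizes differ: {a.size} vs {b.size}")
    rng = _rng_from(seed)
    union = sorted(a.as_set() | b.as_set())
    picked = rng.choice(len(union), size=a.size, replace=False)
    return GeneSignature(tuple(union[i] for i in sorted(picked)), origin="ga")


def mutate(
    a: GeneSignature, universe: Sequence[str], seed: int | np.random.Generator
) -> GeneSignature:
    """Replace one uniformly chosen member with a uniformly chosen outsider."""
    rng = _rng_from(seed)
    outside = sorted(set(universe) - a.as_set())
    if not outside:
        raise ValueError("universe exhausted: no probeset outside the signature")
    drop = int(rng.integers(a.size))
    add = outside[int(rng.integers(len(outside)))]
    ids = list(a.probeset_ids)
    ids[drop] = add
    return GeneSignature(tuple(ids), origin="ga")


def evolve(
    m: ExpressionMatrix,
    annotations: TargetAnnotationTable,
    cfg: GAConfig,
    pred_cfg: PredictionConfig | None = None,
) -> GATrace:
    """Evolve a population of random signatures towards maximal accuracy.

    Generation 0 is seeded with uniform random signatures; each following
    generation carries the elites unchanged and fills the rest with
    crossover/mutation offspring of elites.  Fitness evaluations are
    cached on the sorted probeset tuple, so re-visited signatures cost
    nothing.  Fully deterministic for a fixed ``cfg.seed``.
    """
    if pred_cfg is None:
        pred_cfg = PredictionConfig(k_neighbors=1)
    universe = list(m.probeset_ids)
    if cfg.signature_size > len(universe):
        raise ValueError("signature_size exceeds the probeset universe")
    if cfg.n_elite < 2:
        raise ValueError("elite pool must contain at least 2 individuals")
    rng = np.random.default_rng([cfg.seed, 0x4741])  # stream disjoint from the data generator's

    cache: dict[tuple[str, ...], float] = {}

    def fitness(sig: GeneSignature) -> float:
        key = tuple(sorted(sig.probeset_ids))
        if key not in cache:
            cache[key] = predict_and_score(m, sig, annotations, pred_cfg).accuracy
        return cache[key]

    def random_individual() -> GeneSignature:
        picked = rng.choice(len(universe), size=cfg.signature_size, replace=False)
        return GeneSignature(tuple(universe[i] for i in sorted(picked)), origin="ga")

    population = [random_individual() for _ in range(cfg.population)]
    stats: list[GenerationStats] = []

    def ranked(pop: list[GeneSignature]) -> list[tuple[float, GeneSignature]]:
        scored = [(fitness(s), s) for s in pop]
        # descending fitness; ties by sorted probeset tuple for determinism
        scored.sort(key=lambda t: (-t[0], tuple(sorted(t[1].probeset_ids))))
        return scored

    scored = ranked(population)
    stats.append(_summarise(0, scored))
    for gen in range(1, cfg.generations + 1):
        elites = [s for _, s in scored[: cfg.n_elite]]
        next_pop = list(elites)
        while len(next_pop) < cfg.population:
            if rng.random() < cfg.crossover_rate and len(elites) >= 2:
                i, j = rng.choice(len(elites), size=2, replace=False)
                child = crossover(elites[int(i)], elites[int(j)], rng)
            else:
                parent = elites[int(rng.integers(len(elites)))]
                child = mutate(parent, universe, rng)
            next_pop.append(child)
        scored = ranked(next_pop)
        stats.append(_summarise(gen, scored))
    best_fit, best_sig = scored[0]
    return GATrace(generations=tuple(stats), best_signature=best_sig, best_fitness=best_fit)


def _summarise(gen: int, scored: list[tuple[float, GeneSignature]]) -> GenerationStats:
    fits = [f for f, _ in scored]
    pool = set().union(*(s.as_set() for _, s in scored))
    return GenerationStats(
        generation=gen, best=max(fits), mean=float(np.mean(fits)),
        worst=min(fits), distinct_probesets=len(pool),
    )
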