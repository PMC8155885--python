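"""Binary Artificial Bee Colony (ABC) wrapper feature selection.

A food source is a binary vector over the (channel, band) features; its
fitness is the cross-validated accuracy of a classifier trained on the
selected features.  Each iteration runs three phases:

* employed bees: each source is perturbed against a random neighbor —
  positions where the two agree are kept, disagreeing positions are
  re-drawn uniformly (0 if phi <= 0.5 else 1) — and replaced only by a
  strictly better candidate, otherwise its abandonment counter grows;
* onlooker bees: sources are revisited with probability proportional to
  fitness (roulette wheel), each visit applying the same
  candidate/greedy-replace step;
* scout bees: any source whose abandonment counter exceeds ``limit`` is
  replaced by a fresh random vector.

A best-so-far tracker survives scouting, so the reported optimum never
degrades.  Fitness is deterministic given the fold seed, so evaluations
are cached by bit pattern; an empty (all-zero) selection is
unclassifiable and scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import ParameterError
from .features import FeatureTable, mask_features

logger = logging.getLogger(__name__)

__all__ = ["FoodSource", "ABCConfig", "ABCTrace", "init_sources", "candidate",
           "employed_phase", "selection_probabilities", "onlooker_phase",
           "scout_phase", "run_abc"]

Fitness = Callable[[FeatureTable], float]


@dataclass
class FoodSource:
    """One candidate selection: bits, its fitness, abandonment counter."""

    bits: np.ndarray
    fitness: float = float("nan")
    abandon_count: int = 0

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int8).ravel()


@dataclass
class ABCConfig:
    """Colony parameters: sources (= employed = onlooker bees), the
    abandonment ``limit``, the iteration cap, and the master seed."""

    n_sources: int = 20
    limit: int = 10
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_sources < 2:
            raise ParameterError(f"n_sources must be >= 2, got {self.n_sources}")
        if self.limit < 1:
            raise ParameterError(f"limit must be >= 1, got {self.limit}")
        if self.max_iter < 0:
            raise ParameterError(f"max_iter must be >= 0, got {self.max_iter}")


@dataclass
class ABCTrace:
    """Search result: best-so-far vector, fitness, and per-iteration curve."""

    best_bits: np.ndarray
    best_fitness: float
    curve: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    cache_hits: int = 0


class _CachedFitness:
    """Memoizes a deterministic fitness over bit patterns."""

    def __init__(self, table: FeatureTable, fitness: Fitness):
        self.table = table
        self.fitness = fitness
        self.cache: dict[bytes, float] = {}
        self.n_evaluations = 0
        self.cache_hits = 0

    def __call__(self, bits: np.ndarray) -> float:
        key = np.asarray(bits, dtype=np.int8).tobytes()
        if key in self.cache:
            self.cache_hits += 1
            return self.cache[key]
        if not np.any(bits):
            value = 0.0  # empty selection is unclassifiable
        else:
            value = float(self.fitness(mask_features(self.table, bits)))
        self.cache[key] = value
        self.n_evaluations += 1
        return value


def _random_bits(rng: np.random.Generator, d: int) -> np.ndarray:
    """Fair independent 0/1 draws; all-zero vectors are re-drawn."""
    while True:
        bits = rng.integers(0, 2, size=d, dtype=np.int8)
        if bits.any():
            return bits


def init_sources(cfg: ABCConfig, d: int, rng: np.random.Generator,
                 evaluate: Callable[[np.ndarray], float]) -> list[FoodSource]:
    """Random initial population, each source evaluated once."""
    if d < 1:
        raise ParameterError(f"dimension d must be >= 1, got {d}")
    return [FoodSource(bits := _random_bits(rng, d), evaluate(bits))
            for _ in range(cfg.n_sources)]


def candidate(bits: np.ndarray, neighbor: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Binary neighborhood move: keep agreeing bits, randomize the rest.

    Where current and neighbor agree the bit is kept; where they differ
    a uniform phi in [0, 1] is drawn and the bit becomes 0 if
    phi <= 0.5, else 1.
    """
    bits = np.asarray(bits, dtype=np.int8).ravel()
    neighbor = np.asarray(neighbor, dtype=np.int8).ravel()
    if bits.size != neighbor.size:
        raise ParameterError(
            f"length mismatch: {bits.size} vs {neighbor.size}"
        )
    out = bits.copy()
    differ = bits != neighbor
    if differ.any():
        phi = rng.random(int(differ.sum()))
        out[differ] = np.where(phi <= 0.5, 0, 1).astype(np.int8)
    return out


def _greedy_visit(source: FoodSource, neighbor_bits: np.ndarray,
                  rng: np.random.Generator,
                  evaluate: Callable[[np.ndarray], float]) -> bool:
    """Candidate + strict greedy replacement; returns True on improvement."""
    cand = candidate(source.bits, neighbor_bits, rng)
    fit = evaluate(cand)
    if fit > source.fitness:  # strictly better: ties do not replace
        source.bits = cand
        source.fitness = fit
        source.abandon_count = 0
        return True
    source.abandon_count += 1
    return False


def employed_phase(sources: list[FoodSource], rng: np.random.Generator,
                   evaluate: Callable[[np.ndarray], float]) -> None:
    """Each source attempts one move against a random other source."""
    n = len(sources)
    for i, src in enumerate(sources):
        k = int(rng.integers(0, n - 1))
        if k >= i:
            k += 1
        _greedy_visit(src, sources[k].bits, rng, evaluate)


def selection_probabilities(sources: list[FoodSource]) -> np.ndarray:
    """Fitness-proportional probabilities P_i = fit_i / sum(fit).

    All-zero fitness degenerates to uniform probabilities (logged).
    """
    fit = np.array([s.fitness for s in sources], dtype=float)
    if np.any(fit < 0):
        raise ParameterError("fitness values must be nonnegative")
    total = fit.sum()
    if total == 0:
        logger.info("selection_probabilities: all-zero fitness, uniform fallback")
        return np.full(len(sources), 1.0 / len(sources))
    return fit / total


def onlooker_phase(sources: list[FoodSource], rng: np.random.Generator,
                   evaluate: Callable[[np.ndarray], float]) -> None:
    """n_sources roulette-wheel visits, each a greedy candidate step."""
    n = len(sources)
    probs = selection_probabilities(sources)
    for _ in range(n):
        i = int(rng.choice(n, p=probs))
        if n > 1:
            k = int(rng.integers(0, n - 1))
            if k >= i:
                k += 1
        else:
            k = i
        _greedy_visit(sources[i], sources[k].bits, rng, evaluate)


def scout_phase(sources: list[FoodSource], cfg: ABCConfig,
                rng: np.random.Generator,
                evaluate: Callable[[np.ndarray], float]) -> None:
    """Reinitialize sources whose abandonment counter exceeds the limit.

    Strictly greater than ``limit`` triggers scouting; the best-so-far
    tracker (kept by run_abc) is unaffected.
    """
    for src in sources:
        if src.abandon_count > cfg.limit:
            src.bits = _random_bits(rng, src.bits.size)
            src.fitness = evaluate(src.bits)
            src.abandon_count = 0


def run_abc(table: FeatureTable, cfg: ABCConfig, fitness: Fitness) -> ABCTrace:
    """Full colony loop: employed -> onlooker -> scout, max_iter times.

    ``fitness`` maps a masked FeatureTable to a score in [0, 1] and must
    be deterministic (e.g. cross-validated accuracy with a fixed fold
    seed) so caching is exact.  Fully reproducible from ``cfg.seed``.
    With ``max_iter=0`` the result is the best of the initial population.
    """
    if table.n == 0:
        raise ParameterError("feature table is empty")
    if table.y.nunique() < 2:
        raise ParameterError("feature table must contain two classes")
    rng = np.random.default_rng(cfg.seed)
    evaluate = _CachedFitness(table, fitness)
    sources = init_sources(cfg, table.space.d, rng, evaluate)

    best = max(sources, key=lambda s: s.fitness)
    best_bits = best.bits.copy()
    best_fit = best.fitness
    curve: list[float] = []
    for _ in range(cfg.max_iter):
        employed_phase(sources, rng, evaluate)
        onlooker_phase(sources, rng, evaluate)
        scout_phase(sources, cfg, rng, evaluate)
        for src in sources:
            if src.fitness > best_fit:
                best_fit = src.fitness
                best_bits = src.bits.copy()
        curve.append(best_fit)
    logger.info("run_abc: best fitness %.4f with %d/%d features; "
                "%d evaluations, %d cache hits", best_fit, int(best_bits.sum()),
                best_bits.size, evaluate.n_evaluations, evaluate.cache_hits)
    return ABCTrace(best_bits=best_bits, best_fitness=best_fit, curve=curve,
                    n_evaluations=evaluate.n_evaluations,
                    cache_hits=evaluate.cache_hits)
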