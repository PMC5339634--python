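"""Parabola detection by a univariate marginal distribution algorithm (UMDA).

The optimizer searches over triplets of foreground-pixel indices.  Each
candidate solution (individual) stores three indices into the row-major list
of edge pixels, concatenated as a single bit string of ``3 * L`` bits with
``L = ceil(log2(N))`` bits per gene.  The parabola through the three indexed
pixels is scored by the Hadamard product of its rasterization with the edge
image: the fitness is simply the number of edge pixels the candidate curve
passes through.  UMDA replaces crossover and mutation with an explicit
probability model — the per-bit marginal frequency of the selected
(best-scoring) individuals — from which the next population is sampled.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateTripletError, EmptyImageError
from .geometry import (
    Orientation,
    Parabola,
    PixelPoint,
    evaluate,
    fit_three_points,
    rasterize,
    round_half_away,
)


# ---------------------------------------------------------------------------
# Edge image


@dataclass(frozen=True)
class EdgeImage:
    """A binary image together with its indexed foreground pixels.

    ``foreground_x[ind]``/``foreground_y[ind]`` give the column/row of the
    ``ind``-th foreground pixel in row-major scan order, ``ind`` in
    ``{0, ..., N-1}``.
    """

    grid: np.ndarray
    foreground_y: np.ndarray
    foreground_x: np.ndarray

    @property
    def N(self) -> int:
        return int(self.foreground_y.size)

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    def point(self, ind: int) -> PixelPoint:
        return PixelPoint(x=int(self.foreground_x[ind]), y=int(self.foreground_y[ind]))


def index_pixels(grid: np.ndarray, min_pixels: int = 3) -> EdgeImage:
    """Index the foreground of a binary grid in row-major scan order.

    Raises :class:`EmptyImageError` when fewer than ``min_pixels`` pixels are
    set (three are needed to form one triplet).
    """
    grid = np.ascontiguousarray(np.asarray(grid) != 0)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("grid must be a non-empty 2D array")
    ys, xs = np.nonzero(grid)  # np.nonzero scans row-major
    if ys.size < min_pixels:
        raise EmptyImageError(
            f"{ys.size} foreground pixels; at least {min_pixels} required"
        )
    return EdgeImage(grid=grid, foreground_y=ys, foreground_x=xs)


# ---------------------------------------------------------------------------
# Binary encoding of individuals


def bits_per_gene(N: int) -> int:
    """Number of bits needed to encode indices ``0..N-1``."""
    if N < 1:
        raise ValueError("N must be positive")
    return max(1, math.ceil(math.log2(N)))


def encode(indices: Sequence[int], L: int) -> np.ndarray:
    """Concatenate three indices into a ``3*L`` bit vector, MSB first per gene."""
    bits = np.empty(3 * L, dtype=np.uint8)
    for g, idx in enumerate(indices):
        idx = int(idx)
        if idx < 0 or idx >= (1 << L):
            raise OverflowError(f"index {idx} does not fit in {L} bits")
        for b in range(L):
            bits[g * L + b] = (idx >> (L - 1 - b)) & 1
    return bits


def decode(bits: Sequence[int], L: int) -> Tuple[int, int, int]:
    """Inverse of :func:`encode`; validity against ``N`` is the caller's concern."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size != 3 * L:
        raise ValueError(f"expected {3 * L} bits, got {bits.size}")
    weights = 1 << np.arange(L - 1, -1, -1, dtype=np.int64)
    vals = bits.reshape(3, L).astype(np.int64) @ weights
    return int(vals[0]), int(vals[1]), int(vals[2])


@dataclass
class Individual:
    """One candidate solution: three pixel indices plus their fitness."""

    indices: Tuple[int, int, int]
    bits: np.ndarray
    fitness: int = 0


# ---------------------------------------------------------------------------
# Fitness


def hadamard_fitness(img: EdgeImage, candidate: Parabola, thickness: int = 0) -> int:
    """Matched-pixel count between the candidate's rasterization and the image.

    Equals ``sum(f_binary * I_VS)`` where ``I_VS`` is the virtual-shape image
    of the candidate; computed row-wise without materializing ``I_VS`` when
    ``thickness == 0`` (one curve pixel per row, so the elementwise product
    reduces to indexed lookups).
    """
    if thickness > 0:
        ivs = rasterize(candidate, img.height, img.width, thickness=thickness)
        return int(np.sum(ivs & img.grid))
    if candidate.orientation is Orientation.Y_OF_X:
        flipped = Parabola(candidate.A, candidate.B, candidate.C, Orientation.X_OF_Y)
        return hadamard_fitness(
            EdgeImage(
                grid=np.ascontiguousarray(img.grid.T),
                foreground_y=img.foreground_x,
                foreground_x=img.foreground_y,
            ),
            flipped,
        )
    t = np.arange(img.height)
    s = round_half_away(evaluate(candidate, t))
    ok = (s >= 0) & (s < img.width) & np.isfinite(s)
    return int(img.grid[t[ok], s[ok].astype(np.intp)].sum())


def evaluate_individual(ind: Individual, img: EdgeImage,
                        thickness: int = 0) -> int:
    """Fitness of an individual; every failure mode scores zero.

    Out-of-range indices, repeated indices and geometrically degenerate
    triplets all map to fitness 0 so the evolutionary loop stays total.
    """
    i, j, k = ind.indices
    if max(i, j, k) >= img.N or len({i, j, k}) < 3:
        return 0
    try:
        parab = fit_three_points(img.point(i), img.point(j), img.point(k))
    except DegenerateTripletError:
        return 0
    return hadamard_fitness(img, parab, thickness=thickness)


# ---------------------------------------------------------------------------
# UMDA operators


def select_best(population: List[Individual], rate: float) -> List[Individual]:
    """Top ``ceil(rate * n)`` individuals by fitness; stable on ties."""
    if not 0 < rate <= 1:
        raise ValueError("selection rate must be in (0, 1]")
    n_keep = math.ceil(rate * len(population))
    fitnesses = np.array([ind.fitness for ind in population])
    order = np.argsort(-fitnesses, kind="stable")
    return [population[i] for i in order[:n_keep]]


def estimate_probabilities(selected: List[Individual]) -> np.ndarray:
    """Per-bit marginal frequency of the selected set, clamped away from 0/1.

    Clamping at ``1/(3L)`` keeps every bit mutable and prevents premature
    lock-in of the probability model.
    """
    if not selected:
        raise ValueError("selected set must be non-empty")
    bits = np.stack([ind.bits for ind in selected]).astype(float)
    prob = bits.mean(axis=0)
    margin = 1.0 / bits.shape[1]
    return np.clip(prob, margin, 1.0 - margin)


def sample_population(prob: np.ndarray, n: int, N: int,
                      rng: np.random.Generator) -> List[Individual]:
    """Draw ``n`` individuals with independent Bernoulli bits.

    Genes decoding to an index ``>= N`` are re-drawn from the same marginals
    (up to 16 attempts) and finally replaced by a uniform valid index, which
    avoids the low-index bias a modulo mapping would introduce.
    """
    L = prob.size // 3
    weights = 1 << np.arange(L - 1, -1, -1, dtype=np.int64)
    gene_probs = np.asarray(prob, dtype=float).reshape(3, L)

    bits = (rng.random((n, 3, L)) < gene_probs).astype(np.uint8)
    vals = bits.astype(np.int64) @ weights
    for _ in range(16):
        bad = vals >= N
        if not bad.any():
            break
        redraw = (rng.random((int(bad.sum()), L)) <
                  np.broadcast_to(gene_probs, (n, 3, L))[bad]).astype(np.uint8)
        bits[bad] = redraw
        vals[bad] = redraw.astype(np.int64) @ weights
    bad = vals >= N
    if bad.any():
        uniform = rng.integers(0, N, size=int(bad.sum()))
        vals[bad] = uniform
        bits[bad] = (
            (uniform[:, None] >> np.arange(L - 1, -1, -1)) & 1
        ).astype(np.uint8)

    return [
        Individual(indices=(int(v[0]), int(v[1]), int(v[2])),
                   bits=b.reshape(-1).copy())
        for v, b in zip(vals, bits)
    ]


# ---------------------------------------------------------------------------
# Detection loop


@dataclass
class UMDAParams:
    """Optimizer settings; defaults follow the reference configuration
    (10 individuals, selection rate 0.6, at most 30 generations)."""

    n_individuals: int = 10
    selection_rate: float = 0.6
    max_generations: int = 30
    seed: Optional[int] = None
    thickness: int = 0


@dataclass
class UMDAState:
    """Mutable optimizer state exposed to logging callbacks."""

    prob: np.ndarray
    population: List[Individual]
    generation: int
    best: Optional[Individual]
    best_generation: int


@dataclass
class DetectionResult:
    """Outcome of one detector run.

    ``best_generation`` is the generation at which the global best last
    improved (the "number of iterations" to reach the best solution);
    ``generations`` counts all generations executed.  ``elapsed`` is
    informational only.
    """

    parabola: Optional[Parabola]
    fitness: int
    generations: int
    best_generation: int
    evaluations: int
    elapsed: float = 0.0
    indices: Optional[Tuple[int, int, int]] = None
    history: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "fitness": self.fitness,
            "generations": self.generations,
            "best_generation": self.best_generation,
            "evaluations": self.evaluations,
            "elapsed": self.elapsed,
        }
        if self.parabola is not None:
            d.update(self.parabola.to_dict())
        return d


def run(img: EdgeImage, params: UMDAParams = UMDAParams(),
        rng: Optional[np.random.Generator] = None,
        initial_population: Optional[List[Individual]] = None) -> DetectionResult:
    """Detect the best-matching parabola in an edge image.

    Stops at ``max_generations``, or earlier when the probability model has
    converged (every marginal at its clamp bound) or the population fitness
    has zero spread.  The returned result is the globally best individual
    ever evaluated, refit to its parabola.  Deterministic for a fixed seed.
    """
    if img.N < 3:
        raise EmptyImageError("need at least 3 foreground pixels")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    start = time.perf_counter()
    L = bits_per_gene(img.N)
    n_bits = 3 * L
    margin = 1.0 / n_bits
    prob = np.full(n_bits, 0.5)

    best: Optional[Individual] = None
    best_generation = 0
    history: List[int] = []
    evaluations = 0
    generation = 0

    while generation < params.max_generations:
        generation += 1
        if generation == 1 and initial_population is not None:
            population = initial_population
        else:
            population = sample_population(prob, params.n_individuals, img.N, rng)
        for ind in population:
            ind.fitness = evaluate_individual(ind, img, thickness=params.thickness)
            evaluations += 1
        gen_best = max(population, key=lambda ind: ind.fitness)
        if best is None or gen_best.fitness > best.fitness:
            best = Individual(gen_best.indices, gen_best.bits.copy(),
                              gen_best.fitness)
            best_generation = generation
        history.append(best.fitness)

        selected = select_best(population, params.selection_rate)
        prob = estimate_probabilities(selected)

        # convergence: model pinned at its bounds, or no fitness diversity
        at_bounds = np.all((prob <= margin + 1e-12) | (prob >= 1 - margin - 1e-12))
        fits = np.array([ind.fitness for ind in population])
        if at_bounds or (generation > 1 and fits.std() == 0):
            break

    parab: Optional[Parabola] = None
    if best is not None and best.fitness > 0:
        i, j, k = best.indices
        parab = fit_three_points(img.point(i), img.point(j), img.point(k))
    return DetectionResult(
        parabola=parab,
        fitness=0 if best is None else best.fitness,
        generations=generation,
        best_generation=best_generation,
        evaluations=evaluations,
        elapsed=time.perf_counter() - start,
        indices=None if best is None else best.indices,
        history=history,
    )
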