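"""Genetic algorithm over read bipartitions of one sub-matrix.

An :class:`Individual` is a binary string, one bit per read: bit 0 puts
the read in part 1, bit 1 in part 2.  Fitness is the wMEC cost of the
decoded bipartition with (weighted) majority haplotypes and is minimized
under tournament selection, single-point crossover, independent bit-flip
mutation, a circular burst mutation triggered by stalls, and elitism.

The per-individual operators below define the contract and are what the
unit tests exercise.  :func:`run_ga` applies the same operators
population-wide with vectorized numpy arithmetic so that thousands of
sub-problems stay cheap; its behaviour is pinned by the determinism,
monotonicity and enumeration-oracle tests rather than by bit-for-bit
equivalence with the scalar operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    FragmentMatrix,
    Haplotype,
    InvalidInputError,
    Partition,
    infer_haplotypes,
    wmec_cost,
)

ZERO_ERROR = "zero_error"
MAX_ITERATIONS = "max_iterations"
STALLED = "stalled"


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters; defaults follow the selected setting
    |P|=100, c_r=0.9, m_r=0.05, kappa=0.1*|P|, T=100, theta=ceil(0.25*T)."""

    population_size: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    tournament_size: Optional[int] = None
    max_iterations: int = 100
    stall_limit: Optional[int] = None
    burst_mutation_stall: int = 2
    seed: Optional[int] = None
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InvalidInputError("population_size must be >= 2")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise InvalidInputError("crossover_rate must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise InvalidInputError("mutation_rate must lie in [0, 1]")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        k = self.resolved_tournament_size
        if not 2 <= k <= self.population_size:
            raise InvalidInputError("tournament size must lie in [2, |P|]")
        if self.resolved_stall_limit < 1:
            raise InvalidInputError("stall_limit must be >= 1")

    @property
    def resolved_tournament_size(self) -> int:
        if self.tournament_size is not None:
            return self.tournament_size
        return max(2, math.ceil(0.1 * self.population_size))

    @property
    def resolved_stall_limit(self) -> int:
        if self.stall_limit is not None:
            return self.stall_limit
        return math.ceil(0.25 * self.max_iterations)


@dataclass
class Individual:
    """Binary encoding of a read bipartition with cached fitness."""

    bits: np.ndarray
    fitness: Optional[int] = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8).ravel()
        if not np.isin(self.bits, (0, 1)).all():
            raise InvalidInputError("individual bits must be 0/1")

    def copy(self) -> "Individual":
        return Individual(self.bits.copy(), self.fitness)


@dataclass
class GARunStats:
    best_fitness_per_iteration: list = field(default_factory=list)
    iterations_run: int = 0
    termination_reason: str = MAX_ITERATIONS


@dataclass
class GAResult:
    partition: Partition
    h1: Haplotype
    h2: Haplotype
    stats: GARunStats
    best_fitness: int


# -- scalar operators (contract surface) -----------------------------------


def decode(ind: Individual) -> Partition:
    """Bit 0 -> part 1, bit 1 -> part 2."""
    return Partition(ind.bits.astype(np.int8) + 1)


def evaluate(ind: Individual, sub_matrix: FragmentMatrix, weighted: bool = True) -> int:
    """wMEC cost of the decoded bipartition; cached on the individual."""
    if ind.bits.size != sub_matrix.m:
        raise InvalidInputError("individual length must equal sub-matrix row count")
    if ind.fitness is None:
        part = decode(ind)
        h1, h2, _ = infer_haplotypes(sub_matrix, part, weighted=weighted)
        ind.fitness = wmec_cost(sub_matrix, part, h1, h2)
    return ind.fitness


def tournament_select(
    population: Sequence[Individual], k: int, rng: np.random.Generator
) -> Individual:
    """Best-of-k over a uniform without-replacement sample; ties go to the
    first-sampled candidate."""
    if len(population) == 0:
        raise InvalidInputError("empty population")
    if k > len(population):
        raise InvalidInputError("tournament size exceeds population size")
    idx = rng.choice(len(population), size=k, replace=False)
    fits = [population[i].fitness for i in idx]
    return population[idx[int(np.argmin(fits))]]


def single_point_crossover(
    a: Individual, b: Individual, crossover_rate: float, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """With probability ``crossover_rate`` exchange tails at a uniform cut
    in {1, ..., len-1}; otherwise copy the parents.  Length < 2 always copies."""
    if a.bits.size != b.bits.size:
        raise InvalidInputError("parents must have equal length")
    length = a.bits.size
    if length < 2 or rng.random() >= crossover_rate:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, length))
    ca = np.concatenate([a.bits[:cut], b.bits[cut:]])
    cb = np.concatenate([b.bits[:cut], a.bits[cut:]])
    return Individual(ca), Individual(cb)


def bitflip_mutation(
    ind: Individual, mutation_rate: float, rng: np.random.Generator
) -> Individual:
    """Flip each bit independently with probability ``mutation_rate``."""
    flips = rng.random(ind.bits.size) < mutation_rate
    return Individual(ind.bits ^ flips.astype(np.uint8))


def burst_mutation(
    ind: Individual, mutation_rate: float, rng: np.random.Generator
) -> Individual:
    """Flip bits with probability ``mutation_rate`` inside one random run of
    consecutive positions; the individual is circular, so runs wrap."""
    length = ind.bits.size
    start = int(rng.integers(0, length))
    run = int(rng.integers(1, length + 1))
    pos = (start + np.arange(run)) % length
    flips = rng.random(run) < mutation_rate
    bits = ind.bits.copy()
    bits[pos] ^= flips.astype(np.uint8)
    return Individual(bits)


# -- vectorized fitness ----------------------------------------------------


class FitnessModel:
    """Evaluates the wMEC fitness of a whole population at once.

    For a population matrix ``S`` (one row of part-2 indicators per
    individual) the per-part allele supports are linear in ``S``, so the
    majority haplotypes and the correction counts reduce to two matrix
    products against the sub-matrix's precomputed allele masks.
    """

    def __init__(self, sub_matrix: FragmentMatrix, weighted: bool = True) -> None:
        e = sub_matrix.entries
        self.c1 = (e == 1).astype(np.float64)
        self.c0 = (e == 0).astype(np.float64)
        if weighted:
            self.w1 = np.where(e == 1, sub_matrix.weights, 0.0)
            self.w0 = np.where(e == 0, sub_matrix.weights, 0.0)
        else:
            self.w1, self.w0 = self.c1, self.c0
        self.c1_tot = self.c1.sum(axis=0)
        self.c0_tot = self.c0.sum(axis=0)
        self.w1_tot = self.w1.sum(axis=0)
        self.w0_tot = self.w0.sum(axis=0)

    def population_cost(self, pop: np.ndarray) -> np.ndarray:
        s = pop.astype(np.float64)
        n1_2 = s @ self.w1
        n0_2 = s @ self.w0
        h1 = (self.w1_tot - n1_2) >= (self.w0_tot - n0_2)
        h2 = n1_2 >= n0_2
        cnt1_2 = s @ self.c1
        cnt0_2 = s @ self.c0
        cnt1_1 = self.c1_tot - cnt1_2
        cnt0_1 = self.c0_tot - cnt0_2
        cost = np.where(h1, cnt0_1, cnt1_1).sum(axis=1)
        cost += np.where(h2, cnt0_2, cnt1_2).sum(axis=1)
        return np.rint(cost).astype(np.int64)


# -- the evolutionary loop -------------------------------------------------


def run_ga(
    sub_matrix: FragmentMatrix,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Minimize the wMEC cost over bipartitions of ``sub_matrix``'s reads.

    Terminates on zero error, after ``max_iterations`` generations, or when
    the best fitness has not improved for ``stall_limit`` generations.  The
    elite individual is carried over untouched each generation, so the best
    fitness trace is non-increasing.
    """
    config = config or GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = sub_matrix.m
    psize = config.population_size
    kappa = min(config.resolved_tournament_size, psize)
    model = FitnessModel(sub_matrix, weighted=config.weighted)

    pop = rng.integers(0, 2, size=(psize, m), dtype=np.uint8)
    fits = model.population_cost(pop)
    best = int(fits.argmin())
    best_fit = int(fits[best])
    best_bits = pop[best].copy()

    stats = GARunStats(best_fitness_per_iteration=[best_fit])
    stall = 0
    reason = MAX_ITERATIONS
    iterations = 0

    if best_fit == 0:
        reason = ZERO_ERROR
    else:
        cols = np.arange(m)
        half = psize // 2
        for _ in range(config.max_iterations):
            iterations += 1
            # tournaments: first kappa entries of a random permutation per slot
            order = rng.random((psize, psize)).argsort(axis=1)[:, :kappa]
            winners = order[np.arange(psize), fits[order].argmin(axis=1)]
            selected = pop[winners]

            # single-point crossover on consecutive pairs
            off = selected.copy()
            if m >= 2 and half > 0:
                do = rng.random(half) < config.crossover_rate
                cuts = rng.integers(1, m, size=half)
                swap = (cols[None, :] >= cuts[:, None]) & do[:, None]
                a = selected[0 : 2 * half : 2]
                b = selected[1 : 2 * half : 2]
                off[0 : 2 * half : 2] = np.where(swap, b, a)
                off[1 : 2 * half : 2] = np.where(swap, a, b)

            # classic bit-flip mutation
            off ^= (rng.random((psize, m)) < config.mutation_rate).astype(np.uint8)

            # burst mutation on a circular run, only while stalled
            if stall >= config.burst_mutation_stall:
                starts = rng.integers(0, m, size=psize)
                runs = rng.integers(1, m + 1, size=psize)
                in_run = ((cols[None, :] - starts[:, None]) % m) < runs[:, None]
                off ^= ((rng.random((psize, m)) < config.mutation_rate) & in_run).astype(
                    np.uint8
                )

            # elitism: best-ever individual survives untouched
            off[0] = best_bits
            pop = off
            fits = model.population_cost(pop)
            gen_best = int(fits.argmin())
            if int(fits[gen_best]) < best_fit:
                best_fit = int(fits[gen_best])
                best_bits = pop[gen_best].copy()
                stall = 0
            else:
                stall += 1
            stats.best_fitness_per_iteration.append(best_fit)
            if best_fit == 0:
                reason = ZERO_ERROR
                break
            if stall >= config.resolved_stall_limit:
                reason = STALLED
                break

    stats.iterations_run = iterations
    stats.termination_reason = reason

    # deterministic descent on the returned solution: the GA can occasionally
    # collapse on a poor local optimum when diversity dies early.  The
    # neighbourhood pairs single-bit flips (reassign one read) with suffix
    # flips (reads are position-sorted, so a suffix flip moves or removes an
    # internal phase switch, which no single-bit move can escape).  Pure
    # improvement: cannot worsen any run.
    if best_fit > 0 and m > 1:
        eye = np.eye(m, dtype=np.uint8)
        cols_idx = np.arange(m)
        if m * (m - 1) // 2 <= 8000:
            lo, hi = np.triu_indices(m + 1, k=1)
            keep = ~((lo == 0) & (hi == m))  # full complement is cost-neutral
            lo, hi = lo[keep], hi[keep]
            runs = ((cols_idx[None, :] >= lo[:, None]) & (cols_idx[None, :] < hi[:, None])).astype(np.uint8)
        else:
            runs = (cols_idx[None, :] >= np.arange(1, m)[:, None]).astype(np.uint8)
        # interval moves act on reads in genomic order, whatever the row order
        spans = sub_matrix.read_spans
        order = np.lexsort((cols_idx, spans[:, 1], spans[:, 0]))
        runs_rows = np.zeros_like(runs)
        runs_rows[:, order] = runs
        moves = np.concatenate([eye, runs_rows], axis=0)
        while True:
            candidates = best_bits[None, :] ^ moves
            cand_fits = model.population_cost(candidates)
            j = int(cand_fits.argmin())
            if int(cand_fits[j]) >= best_fit:
                break
            best_fit = int(cand_fits[j])
            best_bits = candidates[j]
            if best_fit == 0:
                break

    partition = decode(Individual(best_bits))
    h1, h2, _ = infer_haplotypes(sub_matrix, partition, weighted=config.weighted)
    assert wmec_cost(sub_matrix, partition, h1, h2) == best_fit
    return GAResult(partition=partition, h1=h1, h2=h2, stats=stats, best_fitness=best_fit)
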