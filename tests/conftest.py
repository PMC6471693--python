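"""Shared fixtures and independent oracles.

The brute-force functions here deliberately use plain Python loops and
re-derive every quantity from first principles, so they stay independent
of the vectorized implementation paths they are used to check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from gaphase.core import MISSING, FragmentMatrix


def matrix_from_strings(rows, weights=None, positions=None):
    """Build a FragmentMatrix from strings over {0,1,-}."""
    entries = np.array(
        [[MISSING if c == "-" else int(c) for c in row] for row in rows], dtype=np.int8
    )
    w = None
    if weights is not None:
        w = np.where(entries != MISSING, np.asarray(weights, dtype=float), 0.0)
    return FragmentMatrix(entries, w, positions)


def naive_cost(matrix: FragmentMatrix, assignment, weighted=True) -> int:
    """Correction count of a bipartition, recomputed with explicit loops:
    per part and column, infer the allele by (weighted) majority with ties
    to 1, then count disagreeing defined entries."""
    m, n = matrix.m, matrix.n
    total = 0
    for part in (1, 2):
        rows = [i for i in range(m) if assignment[i] == part]
        hap = []
        for j in range(n):
            n0 = n1 = 0.0
            for i in rows:
                v = matrix.entries[i, j]
                if v == MISSING:
                    continue
                w = matrix.weights[i, j] if weighted else 1.0
                if v == 1:
                    n1 += w
                else:
                    n0 += w
            hap.append(1 if n1 >= n0 else 0)
        for i in rows:
            for j in range(n):
                v = matrix.entries[i, j]
                if v != MISSING and v != hap[j]:
                    total += 1
    return total


def brute_force_optimum(matrix: FragmentMatrix, weighted=True) -> int:
    """Exhaustive minimum over all label-distinct bipartitions."""
    m = matrix.m
    best = None
    for bits in product((1, 2), repeat=m - 1):
        assignment = (1,) + bits
        cost = naive_cost(matrix, assignment, weighted=weighted)
        if best is None or cost < best:
            best = cost
    return best


def planted_instance(rng, m=10, n=8, error_rate=0.1, coverage_span=None):
    """Random planted-haplotype matrix: each read copies a window of one of
    two complementary haplotypes, with allele flips at ``error_rate``."""
    h1 = rng.integers(0, 2, size=n, dtype=np.int8)
    haps = np.vstack([h1, 1 - h1])
    entries = np.full((m, n), MISSING, dtype=np.int8)
    sources = np.empty(m, dtype=np.int8)
    for i in range(m):
        while True:
            a, b = sorted(rng.integers(0, n, size=2))
            b += 1
            if b - a >= 1:
                break
        src = int(rng.integers(0, 2))
        sources[i] = src + 1
        seg = haps[src, a:b].copy()
        flips = rng.random(b - a) < error_rate
        entries[i, a:b] = seg ^ flips.astype(np.int8)
    covered = (entries != MISSING).any(axis=0)
    entries = entries[:, covered]
    return FragmentMatrix(entries), sources


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
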