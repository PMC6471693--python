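"""Core model for weighted minimum-error-correction (wMEC) haplotype assembly.

A sequencing read restricted to heterozygous SNP positions is a ternary
fragment over {0, 1, MISSING}.  The model collects fragments into an
``m x n`` :class:`FragmentMatrix` with per-entry confidence weights,
bipartitions the rows (:class:`Partition`), infers one haplotype per part
by (weighted) column majority, and scores a candidate solution by the
number of allele corrections it would need (:func:`wmec_cost`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a position not covered by a fragment.
MISSING: int = -1
#: Sentinel for an ambiguous haplotype position; rendered as ``X``.
MASKED: int = -1

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


def _ternary_vector(x, name: str = "vector") -> np.ndarray:
    a = np.asarray(x, dtype=np.int8).ravel()
    bad = ~np.isin(a, (MISSING, 0, 1))
    if bad.any():
        raise InvalidInputError(f"{name} contains values outside {{0, 1, MISSING}}")
    return a


@dataclass
class Haplotype:
    """A length-n allele vector over {0, 1, MASKED}."""

    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = _ternary_vector(self.alleles, "haplotype")

    def __len__(self) -> int:
        return self.alleles.size

    def __eq__(self, other) -> bool:
        return isinstance(other, Haplotype) and np.array_equal(self.alleles, other.alleles)

    def to_string(self) -> str:
        return "".join("X" if v == MASKED else str(int(v)) for v in self.alleles)

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        table = {"0": 0, "1": 1, "X": MASKED, "x": MASKED, "-": MASKED}
        try:
            return cls(np.array([table[c] for c in s.strip()], dtype=np.int8))
        except KeyError as exc:
            raise InvalidInputError(f"bad haplotype character {exc}") from exc


@dataclass
class Partition:
    """Assignment of each read to part 1 or part 2."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int8).ravel()
        if not np.isin(self.assignment, (1, 2)).all():
            raise InvalidInputError("partition labels must be 1 or 2")

    def __len__(self) -> int:
        return self.assignment.size

    def part_rows(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def swapped(self) -> "Partition":
        return Partition(np.int8(3) - self.assignment)


@dataclass
class ColumnTally:
    """Per-part, per-column weight (or count) supporting each allele.

    ``n0[k-1, j]`` / ``n1[k-1, j]`` give the support for allele 0 / 1 in
    column ``j`` restricted to the reads of part ``k``.
    """

    n0: np.ndarray
    n1: np.ndarray


class FragmentMatrix:
    """The m x n ternary fragment matrix plus aligned weights and positions.

    Invariants enforced at construction:

    * ``weights > 0`` exactly where ``entries != MISSING``;
    * genomic column positions strictly increasing (1-based);
    * every row covers at least one column;
    * columns covered by no read are dropped (logged).
    """

    __slots__ = ("entries", "weights", "column_positions", "read_ids")

    def __init__(
        self,
        entries: np.ndarray,
        weights: np.ndarray | None = None,
        column_positions: np.ndarray | None = None,
        read_ids: Sequence[str] | None = None,
    ) -> None:
        entries = np.asarray(entries, dtype=np.int8)
        if entries.ndim != 2:
            raise InvalidInputError("entries must be a 2-D array")
        if not np.isin(entries, (MISSING, 0, 1)).all():
            raise InvalidInputError("entries must lie in {0, 1, MISSING}")
        m, n = entries.shape

        defined = entries != MISSING
        covered_cols = defined.any(axis=0)
        if not covered_cols.all():
            dropped = np.flatnonzero(~covered_cols)
            logger.info("dropping %d column(s) covered by no read: %s", dropped.size, dropped.tolist())

        if weights is None:
            weights = defined.astype(np.float64)
        else:
            weights = np.asarray(weights, dtype=np.float64)
            if weights.shape != entries.shape:
                raise InvalidInputError("weights shape must match entries")
            if ((weights > 0) != defined).any():
                raise InvalidInputError("weights must be > 0 exactly where entries are defined")

        if column_positions is None:
            column_positions = np.arange(1, n + 1, dtype=np.int64)
        else:
            column_positions = np.asarray(column_positions, dtype=np.int64).ravel()
            if column_positions.size != n:
                raise InvalidInputError("column_positions length must equal number of columns")
            if n > 1 and not (np.diff(column_positions) > 0).all():
                raise InvalidInputError("column_positions must be strictly increasing")

        if read_ids is None:
            read_ids = tuple(f"r{i}" for i in range(m))
        else:
            read_ids = tuple(str(r) for r in read_ids)
            if len(read_ids) != m:
                raise InvalidInputError("read_ids length must equal number of rows")
            if len(set(read_ids)) != m:
                raise InvalidInputError("read_ids must be unique")

        if not covered_cols.all():
            entries = entries[:, covered_cols]
            weights = weights[:, covered_cols]
            column_positions = column_positions[covered_cols]

        if entries.shape[1] == 0 or not (entries != MISSING).any(axis=1).all():
            raise InvalidInputError("every read must cover at least one column")

        self.entries = entries
        self.weights = weights
        self.column_positions = column_positions
        self.read_ids = read_ids

    # -- basic geometry ----------------------------------------------------

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]

    @property
    def defined(self) -> np.ndarray:
        return self.entries != MISSING

    def coverage(self) -> np.ndarray:
        """Number of reads covering each column."""
        return self.defined.sum(axis=0)

    @property
    def read_spans(self) -> np.ndarray:
        """(m, 2) leftmost/rightmost covered column index per read."""
        d = self.defined
        left = d.argmax(axis=1)
        right = self.n - 1 - d[:, ::-1].argmax(axis=1)
        return np.column_stack([left, right])

    def row_submatrix(self, rows: np.ndarray) -> tuple["FragmentMatrix", np.ndarray]:
        """Sub-matrix of the given rows restricted to their covered columns.

        Returns the sub-matrix and the original column indices it retains.
        """
        rows = np.asarray(rows)
        e = self.entries[rows]
        cols = np.flatnonzero((e != MISSING).any(axis=0))
        sub = FragmentMatrix(
            e[:, cols],
            self.weights[np.ix_(rows, cols)],
            self.column_positions[cols],
            [self.read_ids[i] for i in rows],
        )
        return sub, cols

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FragmentMatrix)
            and np.array_equal(self.entries, other.entries)
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.column_positions, other.column_positions)
            and self.read_ids == other.read_ids
        )


# -- operations ------------------------------------------------------------


def extended_hamming(f, g) -> int:
    """Number of positions where both vectors are defined yet disagree.

    MASKED haplotype positions behave exactly like MISSING fragment
    positions: they can never contribute a mismatch.
    """
    fa = f.alleles if isinstance(f, Haplotype) else _ternary_vector(f, "f")
    ga = g.alleles if isinstance(g, Haplotype) else _ternary_vector(g, "g")
    if fa.size != ga.size:
        raise InvalidInputError(f"length mismatch: {fa.size} != {ga.size}")
    return int(((fa != ga) & (fa != MISSING) & (ga != MISSING)).sum())


def fragments_in_conflict(f, g) -> bool:
    """True iff some position is defined in both fragments with different values."""
    return extended_hamming(f, g) > 0


def column_kind(matrix: FragmentMatrix, j: int) -> str:
    """Classify column ``j`` (0-based) as homozygous or heterozygous.

    Homozygous: the defined values are all 0 or all 1.  Heterozygous:
    both alleles occur.
    """
    if not 0 <= j < matrix.n:
        raise InvalidInputError(f"column index {j} out of range [0, {matrix.n})")
    col = matrix.entries[:, j]
    has0 = (col == 0).any()
    has1 = (col == 1).any()
    return HETEROZYGOUS if (has0 and has1) else HOMOZYGOUS


def infer_haplotypes(
    matrix: FragmentMatrix,
    partition: Partition,
    weighted: bool = True,
) -> tuple[Haplotype, Haplotype, ColumnTally]:
    """Column-majority haplotypes for each part of a read bipartition.

    The allele at column ``j`` of part ``k`` is 1 iff the (weighted when
    ``weighted``) support for allele 1 is >= the support for allele 0.
    Ties — including columns uncovered by part ``k``, where both supports
    are 0 — resolve to 1; downstream masking handles uncovered columns.
    """
    if len(partition) != matrix.m:
        raise InvalidInputError("partition length must equal number of reads")
    src = matrix.weights if weighted else matrix.defined.astype(np.float64)
    w1 = np.where(matrix.entries == 1, src, 0.0)
    w0 = np.where(matrix.entries == 0, src, 0.0)
    in2 = (partition.assignment == 2).astype(np.float64)
    n1_2 = in2 @ w1
    n0_2 = in2 @ w0
    n1 = np.vstack([w1.sum(axis=0) - n1_2, n1_2])
    n0 = np.vstack([w0.sum(axis=0) - n0_2, n0_2])
    h = (n1 >= n0).astype(np.int8)
    return Haplotype(h[0]), Haplotype(h[1]), ColumnTally(n0=n0, n1=n1)


def wmec_cost(
    matrix: FragmentMatrix,
    partition: Partition,
    h1: Haplotype,
    h2: Haplotype,
) -> int:
    """Total number of allele corrections: sum over reads of the extended
    Hamming distance to the haplotype of the read's part."""
    if len(h1) != matrix.n or len(h2) != matrix.n:
        raise InvalidInputError("haplotype width must equal matrix width")
    if len(partition) != matrix.m:
        raise InvalidInputError("partition length must equal number of reads")
    hap_rows = np.where(
        (partition.assignment == 1)[:, None], h1.alleles[None, :], h2.alleles[None, :]
    )
    mism = (matrix.entries != hap_rows) & (matrix.entries != MISSING) & (hap_rows != MISSING)
    return int(mism.sum())
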