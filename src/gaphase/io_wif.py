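"""Readers and writers: WIF fragment files, ground-truth haplotypes, and
the block-structured haplotype output.

WIF dialect: one read per line; each covered SNP contributes a
``position base allele phred`` field; fields are separated by ``:`` and
the line is terminated by a ``# <score> : <name>`` comment, e.g.::

    10 A 1 27 : 20 C 1 33 : # 60 : read_0

Positions are 1-based and strictly increasing within a read.  The truth
format is three lines: the two haplotype strings over {0,1} followed by
the whitespace-separated positions.  Assembled haplotypes are written as
5-line stanzas per block: a ``BLOCK`` header, the two {0,1,X} strings,
and the positions line.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable

import numpy as np

from .assembly import AssemblyResult, BlockResult
from .core import MISSING, FragmentMatrix, Haplotype, InvalidInputError

logger = logging.getLogger(__name__)

_ALLELE_BASE = {0: "A", 1: "C"}  # placeholder nucleotides; parsers ignore them


class WifParseError(InvalidInputError):
    """Malformed WIF input; message carries the offending line number."""


def parse_wif(stream: IO[str]) -> FragmentMatrix:
    """Parse a WIF stream into a :class:`FragmentMatrix`.

    Reads covering fewer than two columns are retained (they cannot
    constrain phase and are logged).  Comment fields contribute only the
    read name; nothing else is preserved.
    """
    reads: list[list[tuple[int, int, int]]] = []
    names: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        body, _, comment = line.partition("#")
        entries: list[tuple[int, int, int]] = []
        for f_no, fld in enumerate(body.split(":")):
            fld = fld.strip()
            if not fld:
                continue
            toks = fld.split()
            if len(toks) != 4:
                raise WifParseError(
                    f"line {lineno}: field {f_no + 1} has {len(toks)} tokens, expected 4"
                )
            pos_s, _base, allele_s, phred_s = toks
            try:
                pos = int(pos_s)
                phred = int(phred_s)
            except ValueError as exc:
                raise WifParseError(f"line {lineno}: non-integer position/phred") from exc
            if allele_s not in ("0", "1"):
                raise WifParseError(f"line {lineno}: allele must be 0 or 1, got {allele_s!r}")
            if phred < 0:
                raise WifParseError(f"line {lineno}: negative phred weight")
            if entries and pos <= entries[-1][0]:
                raise WifParseError(f"line {lineno}: positions not strictly increasing")
            entries.append((pos, int(allele_s), phred))
        if not entries:
            raise WifParseError(f"line {lineno}: read covers no position")
        name = ""
        if comment:
            toks = [t.strip() for t in comment.split(":")]
            if len(toks) >= 2 and toks[-1]:
                name = toks[-1]
        if not name:
            name = f"read_{lineno}"
        reads.append(entries)
        names.append(name)
    if not reads:
        raise WifParseError("empty WIF input")

    # de-duplicate names, preserving order
    seen: dict[str, int] = {}
    for i, name in enumerate(names):
        if name in seen:
            seen[name] += 1
            names[i] = f"{name}.{seen[name]}"
        else:
            seen[name] = 0

    positions = np.array(sorted({p for r in reads for p, _, _ in r}), dtype=np.int64)
    m, n = len(reads), positions.size
    entries_arr = np.full((m, n), MISSING, dtype=np.int8)
    weights = np.zeros((m, n), dtype=np.float64)
    for i, read in enumerate(reads):
        if len(read) < 2:
            logger.info("read %s covers <2 columns and cannot constrain phase", names[i])
        for pos, allele, phred in read:
            j = int(np.searchsorted(positions, pos))
            entries_arr[i, j] = allele
            weights[i, j] = max(phred, 1)  # weight must be positive where defined
    return FragmentMatrix(entries_arr, weights, positions, names)


def write_wif(matrix: FragmentMatrix, stream: IO[str]) -> None:
    """Write a matrix in the WIF dialect above (inverse of :func:`parse_wif`)."""
    for i in range(matrix.m):
        cols = np.flatnonzero(matrix.defined[i])
        fields = []
        for j in cols:
            allele = int(matrix.entries[i, j])
            fields.append(
                f"{int(matrix.column_positions[j])} {_ALLELE_BASE[allele]} "
                f"{allele} {int(round(matrix.weights[i, j]))}"
            )
        stream.write(" : ".join(fields) + f" : # 60 : {matrix.read_ids[i]}\n")


# -- assembled haplotypes --------------------------------------------------


def write_haplotypes(result: AssemblyResult, stream: IO[str]) -> None:
    """One 5-line stanza per block, ordered by leftmost position."""
    for block in result.blocks:
        stream.write(
            f"BLOCK {int(block.positions[0])} {int(block.positions[-1])} "
            f"{block.positions.size} {block.cost}\n"
        )
        stream.write(block.h1.to_string() + "\n")
        stream.write(block.h2.to_string() + "\n")
        stream.write(" ".join(str(int(p)) for p in block.positions) + "\n")


def parse_haplotypes(stream: IO[str]) -> list[dict]:
    """Parse stanzas written by :func:`write_haplotypes` into dicts with
    keys ``positions`` (int64 array), ``h1``, ``h2`` (:class:`Haplotype`)
    and ``cost``."""
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if len(lines) % 4 != 0:
        raise InvalidInputError("haplotype file must consist of 4-line block stanzas")
    out = []
    for i in range(0, len(lines), 4):
        header = lines[i].split()
        if header[0] != "BLOCK" or len(header) != 5:
            raise InvalidInputError(f"bad BLOCK header: {lines[i]!r}")
        h1 = Haplotype.from_string(lines[i + 1])
        h2 = Haplotype.from_string(lines[i + 2])
        positions = np.array([int(t) for t in lines[i + 3].split()], dtype=np.int64)
        if not (len(h1) == len(h2) == positions.size == int(header[3])):
            raise InvalidInputError(f"inconsistent stanza starting at line {i + 1}")
        out.append({"positions": positions, "h1": h1, "h2": h2, "cost": int(header[4])})
    return out


# -- ground truth ----------------------------------------------------------


def write_truth(
    positions: Iterable[int], h1: Haplotype, h2: Haplotype, stream: IO[str]
) -> None:
    stream.write(h1.to_string() + "\n")
    stream.write(h2.to_string() + "\n")
    stream.write(" ".join(str(int(p)) for p in positions) + "\n")


def parse_truth(stream: IO[str]) -> tuple[np.ndarray, Haplotype, Haplotype]:
    """Two {0,1} lines plus a positions line -> (positions, h1, h2)."""
    lines = [ln.strip() for ln in stream if ln.strip()]
    if len(lines) != 3:
        raise InvalidInputError("truth file must have exactly 3 non-empty lines")
    h1 = Haplotype.from_string(lines[0])
    h2 = Haplotype.from_string(lines[1])
    positions = np.array([int(t) for t in lines[2].split()], dtype=np.int64)
    if not (len(h1) == len(h2) == positions.size):
        raise InvalidInputError("truth lines have mismatching lengths")
    return positions, h1, h2
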