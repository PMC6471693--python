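"""Divide-and-conquer assembly of haplotype blocks.

Pipeline per input matrix: detect haplotype blocks (connected components
of read/column co-coverage), choose a chunk size ``gamma`` equal to each
block's rounded mean coverage, split the block's reads into ``floor(m /
gamma)`` consecutive chunks, solve each chunk's wMEC sub-problem with an
independent GA, then orient and merge the per-chunk haplotype pairs,
assign homozygous columns, and mask positions covered by only one side
of the final bipartition.

Sub-problems may be dispatched to a process pool; results are merged in
sub-problem order and every GA draws from a stream derived from (seed,
block index, sub-problem index), so output is identical for any worker
count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MASKED,
    MISSING,
    FragmentMatrix,
    Haplotype,
    Partition,
    infer_haplotypes,
    wmec_cost,
)
from .ga import GAConfig, GARunStats, run_ga

logger = logging.getLogger(__name__)


@dataclass
class Block:
    """Maximal set of columns connected through read co-coverage."""

    column_indices: np.ndarray
    read_indices: np.ndarray
    mean_coverage: float


@dataclass
class SubSolution:
    """Solved sub-problem: haplotypes over the chunk's covered columns."""

    columns: np.ndarray          # global column indices covered by the chunk
    h1: np.ndarray               # int8 alleles over `columns`
    h2: np.ndarray
    assignment: np.ndarray       # 1/2 per chunk read
    part_coverage: np.ndarray    # (2, len(columns)) defined-entry counts per part
    stats: GARunStats
    cost: int
    entries: np.ndarray | None = None  # chunk reads over `columns` (orientation evidence)


@dataclass
class BlockResult:
    positions: np.ndarray        # genomic positions of the block's columns
    column_indices: np.ndarray
    read_indices: np.ndarray     # block reads in chunk order
    assignment: np.ndarray       # final 1/2 label per read (chunk order)
    h1: Haplotype
    h2: Haplotype
    gamma: int
    n_subproblems: int
    stats: list = field(default_factory=list)
    cost: int = 0


@dataclass
class AssemblyResult:
    blocks: list
    total_cost: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


# -- block detection and splitting -----------------------------------------


def detect_blocks(matrix: FragmentMatrix) -> list[Block]:
    """Connected components of the read-column coverage graph, ordered by
    leftmost column; every column lands in exactly one block."""
    n = matrix.n
    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    defined = matrix.defined
    for i in range(matrix.m):
        cols = np.flatnonzero(defined[i])
        r0 = find(cols[0])
        for c in cols[1:]:
            rc = find(c)
            if rc != r0:
                parent[rc] = r0
    roots = np.array([find(c) for c in range(n)])

    read_root = np.array([find(int(defined[i].argmax())) for i in range(matrix.m)])
    blocks = []
    for root in np.unique(roots):
        cols = np.flatnonzero(roots == root)
        reads = np.flatnonzero(read_root == root)
        cov = defined[np.ix_(reads, cols)].sum()
        blocks.append(
            Block(
                column_indices=cols,
                read_indices=reads,
                mean_coverage=float(cov) / cols.size,
            )
        )
    blocks.sort(key=lambda b: int(b.column_indices[0]))
    return blocks


def compute_gamma(block: Block) -> int:
    """Chunk size: mean block coverage, rounded half-up, floored at 2."""
    return max(2, int(np.floor(block.mean_coverage + 0.5)))


def split_block(matrix: FragmentMatrix, block: Block, gamma: int) -> list[np.ndarray]:
    """Split the block's reads (sorted by span) into consecutive chunks of
    ``gamma``; a remainder shorter than ``gamma/2`` is folded into the last
    full chunk, otherwise it forms a smaller final chunk."""
    spans = matrix.read_spans[block.read_indices]
    order = np.lexsort((block.read_indices, spans[:, 1], spans[:, 0]))
    reads = block.read_indices[order]
    m = reads.size
    full = m // gamma
    if full == 0:
        return [reads]
    chunks = [reads[i * gamma : (i + 1) * gamma] for i in range(full)]
    rem = m % gamma
    if rem:
        if rem < gamma / 2:
            chunks[-1] = np.concatenate([chunks[-1], reads[full * gamma :]])
        else:
            chunks.append(reads[full * gamma :])
    return chunks


# -- sub-problem solving ---------------------------------------------------


def _part_coverage(sub: FragmentMatrix, assignment: np.ndarray) -> np.ndarray:
    d = sub.defined
    in2 = assignment == 2
    return np.vstack([d[~in2].sum(axis=0), d[in2].sum(axis=0)])


#: GA runs per sub-problem; the best result wins.  A single run collapses on
#: a poor local optimum a few percent of the time, and one bad sub-solution
#: can mis-phase a whole block, so the failure probability is squared.
_GA_RESTARTS = 2


def _best_of(sub, config, rng, restarts: int = _GA_RESTARTS):
    best = None
    for _ in range(max(1, restarts)):
        res = run_ga(sub, config, rng)
        if best is None or res.best_fitness < best.best_fitness:
            best = res
        if best.best_fitness == 0:
            break
    return best


def solve_subproblem(
    matrix: FragmentMatrix,
    read_indices: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator | None = None,
) -> SubSolution:
    """Run the GA on the sub-matrix of the given reads restricted to their
    covered columns; all phased positions are treated as heterozygous."""
    sub, cols = matrix.row_submatrix(read_indices)
    res = _best_of(sub, config, rng)
    return SubSolution(
        columns=cols,
        h1=res.h1.alleles,
        h2=res.h2.alleles,
        assignment=res.partition.assignment,
        part_coverage=_part_coverage(sub, res.partition.assignment),
        stats=res.stats,
        cost=res.best_fitness,
        entries=sub.entries,
    )


def _task_rng(entropy: int, block_index: int, sub_index: int) -> np.random.Generator:
    # stream depends only on (seed, block, sub-problem), never on scheduling
    return np.random.default_rng(
        np.random.SeedSequence(entropy, spawn_key=(block_index, sub_index))
    )


def _ga_task(args):
    sub, config, entropy, block_index, sub_index = args
    try:
        res = _best_of(sub, config, _task_rng(entropy, block_index, sub_index))
    except Exception as exc:  # surfaced with sub-problem identity by the caller
        return (block_index, sub_index, exc)
    return (block_index, sub_index, (res.partition.assignment, res.h1.alleles, res.h2.alleles, res.stats, res.best_fitness))


# -- merging ---------------------------------------------------------------


#: cap on the per-incidence weight of already-merged evidence, so a deep
#: well-phased context cannot be vetoed by a single ambiguous column, nor a
#: single erroneous prior read decide a junction.
_MARGIN_CAP = 5


#: minimum number of chunk reads that must straddle a column boundary for
#: the chunk's own solution to be trusted across it; thinner waists are cut
#: and the pieces oriented independently against the merged context.
_MIN_BRIDGE = 3


def _read_segments(entries: np.ndarray, min_bridge: int = _MIN_BRIDGE) -> list[np.ndarray]:
    """Split a chunk's reads into phase-coherent segments.

    A chunk solution links the phase of two column ranges only through
    the reads straddling the boundary between them.  Where fewer than
    ``min_bridge`` chunk reads do so (zero for genuinely disconnected
    components), a single sequencing error can silently invert the
    solution's relative phase, so the chunk is cut there and each side is
    oriented against the merged context separately.  Reads crossing a
    cut join the segment holding most of their covered columns (ties go
    left).  Segments are returned in leftmost-column order.
    """
    m, n = entries.shape
    defined = entries != MISSING
    left = defined.argmax(axis=1)
    right = n - 1 - defined[:, ::-1].argmax(axis=1)
    if n == 1:
        return [np.arange(m)]
    # bridge[c] = reads covering something <= c and something >= c+1
    bridge = np.array([int(((left <= c) & (right >= c + 1)).sum()) for c in range(n - 1)])
    col_seg = np.concatenate([[0], np.cumsum(bridge < min_bridge)])
    read_seg = np.empty(m, dtype=np.int64)
    for i in range(m):
        segs = col_seg[defined[i]]
        read_seg[i] = np.bincount(segs).argmax()

    # within each piece, reads are phase-linked only through shared columns;
    # a piece may still fall apart into several co-coverage components
    out: list[np.ndarray] = []
    for s in range(int(col_seg[-1]) + 1):
        piece = np.flatnonzero(read_seg == s)
        if piece.size == 0:
            continue
        parent = np.arange(piece.size)

        def find(x: int) -> int:
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        for c in range(n):
            covering = np.flatnonzero(defined[piece, c])
            for other in covering[1:]:
                ra, rb = find(int(covering[0])), find(int(other))
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(i) for i in range(piece.size)])
        for root in np.unique(roots):
            out.append(piece[roots == root])
    out.sort(key=lambda seg: int(left[seg].min()))
    return out


def orient_and_merge(
    subsolutions: list[SubSolution], block_columns: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Chain consecutive sub-solutions into one haplotype pair per block.

    Running per-(part, column) allele votes accumulate the reads of the
    sub-solutions merged so far.  Each incoming sub-solution is split
    into its read connected components (an internally disconnected chunk
    has no phase linking its components); each component is kept or
    label-swapped, whichever agrees better with the current vote
    majorities.  Agreement is scored read incidence by read incidence and
    weighted by the merged majority margin (capped), so a column phased
    by many prior reads outweighs one backed by a single, possibly
    erroneous, read.  Ties and empty overlaps keep identity (the latter
    logged: phase between the pieces is then arbitrary).

    Returns the vote-majority haplotype pair ((2, n_block) int8, MISSING
    where no votes) and one boolean flip flag per read of each
    sub-solution.
    """
    n = block_columns.size
    votes0 = np.zeros((2, n))
    votes1 = np.zeros((2, n))
    read_flips = [np.zeros(sol.assignment.size, dtype=bool) for sol in subsolutions]

    # orientable units: (leftmost column, sub-problem index, reads) for each
    # phase-coherent segment of each sub-solution, swept left to right so a
    # segment is oriented only after its neighbourhood has voted
    units: list[tuple[int, int, np.ndarray]] = []
    locs = [np.searchsorted(block_columns, sol.columns) for sol in subsolutions]
    for si, sol in enumerate(subsolutions):
        segs = (
            _read_segments(sol.entries)
            if sol.entries is not None
            else [np.arange(sol.assignment.size)]
        )
        for seg in segs:
            if sol.entries is not None:
                leftmost = int(locs[si][(sol.entries[seg] != MISSING).argmax(axis=1).min()])
            else:
                leftmost = int(locs[si][0])
            units.append((leftmost, si, seg))
    units.sort(key=lambda u: (u[0], u[1]))

    for ui, (_, si, seg) in enumerate(units):
        sol = subsolutions[si]
        loc = locs[si]
        margin = np.minimum(np.abs(votes1 - votes0), _MARGIN_CAP)
        consensus = np.where(votes1 >= votes0, 1, 0).astype(np.int8)
        consensus[(votes1 + votes0) == 0] = MISSING
        if sol.entries is not None:
            e = sol.entries[seg]
            defined = e != MISSING
            own_part = sol.assignment[seg] - 1
            own = consensus[own_part][:, loc]
            other = consensus[1 - own_part][:, loc]
            w_own = margin[own_part][:, loc]
            w_other = margin[1 - own_part][:, loc]
            usable_id = defined & (own != MISSING)
            usable_sw = defined & (other != MISSING)
            net_id = float((np.where(e == own, w_own, -w_own) * usable_id).sum())
            net_sw = float((np.where(e == other, w_other, -w_other) * usable_sw).sum())
            if ui > 0 and not (usable_id.any() or usable_sw.any()):
                logger.debug(
                    "no merged context for a segment of sub-problem %d; keeping identity",
                    si,
                )
        else:
            h_pair = np.vstack([sol.h1, sol.h2])
            cons = consensus[:, loc]
            w = margin[:, loc]
            ok = (cons != MISSING) & (h_pair != MISSING)
            net_id = float((np.where(h_pair == cons, w, -w) * ok).sum())
            ok_sw = (cons[::-1] != MISSING) & (h_pair != MISSING)
            net_sw = float(
                (np.where(h_pair == cons[::-1], w[::-1], -w[::-1]) * ok_sw).sum()
            )
        flip = net_sw > net_id
        read_flips[si][seg] = flip

        # add this segment's votes under its chosen orientation
        if sol.entries is not None:
            e = sol.entries[seg]
            part = sol.assignment[seg] - 1
            if flip:
                part = 1 - part
            for k in (0, 1):
                rows = e[part == k]
                if rows.size:
                    votes0[k, loc] += (rows == 0).sum(axis=0)
                    votes1[k, loc] += (rows == 1).sum(axis=0)
        else:
            halves = (sol.h2, sol.h1) if flip else (sol.h1, sol.h2)
            covers = sol.part_coverage[::-1] if flip else sol.part_coverage
            for k in (0, 1):
                votes0[k, loc] += covers[k] * (halves[k] == 0)
                votes1[k, loc] += covers[k] * (halves[k] == 1)

    hap = np.where(votes1 >= votes0, 1, 0).astype(np.int8)
    hap[(votes1 + votes0) == 0] = MISSING
    return hap, read_flips


def correct_homozygous_sites(hap: np.ndarray, block_entries: np.ndarray) -> np.ndarray:
    """Assign both haplotypes the shared value at columns homozygous in the
    block's sub-matrix (all defined values identical)."""
    has0 = (block_entries == 0).any(axis=0)
    has1 = (block_entries == 1).any(axis=0)
    homozygous = ~(has0 & has1)
    value = has1.astype(np.int8)
    out = hap.copy()
    out[0, homozygous] = value[homozygous]
    out[1, homozygous] = value[homozygous]
    return out


def mask_ambiguous(
    hap: np.ndarray, block_entries: np.ndarray, assignment: np.ndarray
) -> np.ndarray:
    """Mask h_k at every column covered by no read of part k: such a
    position is phased by only one side of the bipartition."""
    d = block_entries != MISSING
    out = hap.copy()
    for k in (1, 2):
        cov = d[assignment == k].sum(axis=0) if (assignment == k).any() else np.zeros(
            block_entries.shape[1], dtype=np.int64
        )
        out[k - 1, cov == 0] = MASKED
    return out


def _refine_block_partition(
    sub: FragmentMatrix, assignment: np.ndarray, weighted: bool = True, max_rounds: int = 30
) -> np.ndarray:
    """Descend on the block-level wMEC cost from the merged bipartition.

    Moves: flipping a suffix of the position-sorted reads (relocates or
    removes a residual phase switch left by a mis-oriented junction) and
    flipping single reads.  Both are evaluated incrementally from
    per-part column tallies, so a full sweep costs O(total entries).
    Haplotypes follow the (weighted) column majority throughout; the cost
    is the plain correction count.  Deterministic and cost-monotone.
    """
    m, n = sub.m, sub.n
    if m < 2:
        return assignment
    e = sub.entries
    w = sub.weights if weighted else sub.defined.astype(np.float64)
    rows = [np.flatnonzero(e[i] != MISSING) for i in range(m)]
    vals = [e[i, r] for i, r in zip(range(m), rows)]
    wts = [w[i, r] for i, r in zip(range(m), rows)]

    assignment = assignment.copy()
    cnt = np.zeros((2, 2, n))  # [part, allele, column] read counts
    wgt = np.zeros((2, 2, n))  # weighted tallies for the majority call
    for i in range(m):
        k = assignment[i] - 1
        cnt[k, vals[i], rows[i]] += 1
        wgt[k, vals[i], rows[i]] += wts[i]

    def col_cost(cols: np.ndarray) -> float:
        h = wgt[:, 1, cols] >= wgt[:, 0, cols]
        return float(np.where(h, cnt[:, 0, cols], cnt[:, 1, cols]).sum())

    def move(i: int) -> None:
        k = assignment[i] - 1
        cnt[k, vals[i], rows[i]] -= 1
        wgt[k, vals[i], rows[i]] -= wts[i]
        cnt[1 - k, vals[i], rows[i]] += 1
        wgt[1 - k, vals[i], rows[i]] += wts[i]
        assignment[i] = 3 - assignment[i]

    base = col_cost(np.arange(n))
    for _ in range(max_rounds):
        improved = False
        # suffix flips, evaluated in one right-to-left sweep
        deltas = np.empty(m)
        running = 0.0
        for i in range(m - 1, -1, -1):
            before = col_cost(rows[i])
            move(i)
            running += col_cost(rows[i]) - before
            deltas[i] = running
        for i in range(m):  # restore
            move(i)
        best = int(deltas.argmin())
        if deltas[best] < -1e-9:
            for i in range(best, m):
                move(i)
            base += deltas[best]
            improved = True
        # single-read flips, first-improvement sweeps until stable
        for _ in range(10):
            changed = False
            for i in range(m):
                before = col_cost(rows[i])
                move(i)
                delta = col_cost(rows[i]) - before
                if delta < -1e-9:
                    base += delta
                    changed = True
                    improved = True
                else:
                    move(i)
            if not changed:
                break
        if not improved:
            break
    return assignment


def _merge_block(
    matrix: FragmentMatrix,
    block: Block,
    gamma: int,
    chunks: list[np.ndarray],
    sols: list[SubSolution],
) -> BlockResult:
    bcols = block.column_indices
    _, read_flips = orient_and_merge(sols, bcols)

    read_order = np.concatenate(chunks)
    assignment = np.concatenate(
        [np.where(f, 3 - s.assignment, s.assignment) for s, f in zip(sols, read_flips)]
    ).astype(np.int8)

    bsub, sub_cols = matrix.row_submatrix(read_order)
    assert np.array_equal(sub_cols, bcols)

    # reads in position order so suffix moves correspond to phase switches
    pos_order = np.lexsort((np.arange(read_order.size), bsub.read_spans[:, 1], bsub.read_spans[:, 0]))
    refined = _refine_block_partition(
        FragmentMatrix(
            bsub.entries[pos_order],
            bsub.weights[pos_order],
            bsub.column_positions,
            [bsub.read_ids[i] for i in pos_order],
        ),
        assignment[pos_order],
    )
    assignment[pos_order] = refined

    # final haplotypes: weighted majority over the merged bipartition
    h1m, h2m, _ = infer_haplotypes(bsub, Partition(assignment))
    hap = np.vstack([h1m.alleles, h2m.alleles])
    block_entries = bsub.entries
    hap = correct_homozygous_sites(hap, block_entries)
    hap = mask_ambiguous(hap, block_entries, assignment)
    h1, h2 = Haplotype(hap[0]), Haplotype(hap[1])
    cost = wmec_cost(bsub, Partition(assignment), h1, h2)
    return BlockResult(
        positions=matrix.column_positions[bcols],
        column_indices=bcols,
        read_indices=read_order,
        assignment=assignment,
        h1=h1,
        h2=h2,
        gamma=gamma,
        n_subproblems=len(sols),
        stats=[s.stats for s in sols],
        cost=cost,
    )


# -- top-level driver ------------------------------------------------------


def assemble(
    matrix: FragmentMatrix,
    config: GAConfig | None = None,
    workers: int = 1,
) -> AssemblyResult:
    """Assemble one haplotype pair per detected block.

    Blocks are processed independently; their sub-problems run on
    ``workers`` processes (sequentially when ``workers == 1``) and merge
    in sub-problem order, so results do not depend on the worker count.
    """
    config = config or GAConfig()
    entropy = config.seed if config.seed is not None else int(
        np.random.SeedSequence().entropy
    ) % (2**63)

    blocks = detect_blocks(matrix)
    plans = []
    tasks = []
    for bi, block in enumerate(blocks):
        gamma = compute_gamma(block)
        chunks = split_block(matrix, block, gamma)
        plans.append((block, gamma, chunks))
        for si, chunk in enumerate(chunks):
            sub, cols = matrix.row_submatrix(chunk)
            tasks.append((bi, si, sub, cols))

    raw: dict[tuple[int, int], tuple] = {}
    if workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for bi, si, payload in pool.map(
                _ga_task,
                [(sub, config, entropy, bi, si) for bi, si, sub, _ in tasks],
                chunksize=max(1, len(tasks) // (4 * workers)),
            ):
                if isinstance(payload, Exception):
                    raise RuntimeError(
                        f"sub-problem {si} of block {bi} failed: {payload!r}"
                    ) from payload
                raw[(bi, si)] = payload
    else:
        for bi, si, sub, _ in tasks:
            res = _best_of(sub, config, _task_rng(entropy, bi, si))
            raw[(bi, si)] = (
                res.partition.assignment,
                res.h1.alleles,
                res.h2.alleles,
                res.stats,
                res.best_fitness,
            )

    sols_by_block: dict[int, list[SubSolution]] = {bi: [] for bi in range(len(blocks))}
    for bi, si, sub, cols in tasks:
        assignment, h1, h2, stats, cost = raw[(bi, si)]
        sols_by_block[bi].append(
            SubSolution(
                columns=cols,
                h1=h1,
                h2=h2,
                assignment=assignment,
                part_coverage=_part_coverage(sub, assignment),
                stats=stats,
                cost=cost,
                entries=sub.entries,
            )
        )

    results = [
        _merge_block(matrix, block, gamma, chunks, sols_by_block[bi])
        for bi, (block, gamma, chunks) in enumerate(plans)
    ]
    return AssemblyResult(blocks=results, total_cost=int(sum(b.cost for b in results)))
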