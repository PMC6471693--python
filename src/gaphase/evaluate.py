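"""Metrics: haplotype error rate (HE), block agreement, and average-best-
fitness (ABF) curves.

HE is the percentage of unmasked haplotype alleles at truth-heterozygous
positions that differ from the ground truth, minimized over the two
label assignments independently per block (blocks are phased
independently).  MASKED positions are abstentions: excluded from both
numerator and denominator and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MASKED, Haplotype, InvalidInputError
from .ga import GARunStats


@dataclass
class EvalReport:
    pooled_he: float
    per_block_he: list = field(default_factory=list)
    evaluated_positions: int = 0
    mismatches: int = 0
    masked_positions: int = 0

    def to_dict(self) -> dict:
        return {
            "pooled_he_percent": self.pooled_he,
            "per_block_he_percent": self.per_block_he,
            "evaluated_positions": self.evaluated_positions,
            "mismatches": self.mismatches,
            "masked_positions": self.masked_positions,
        }


def _block_arrays(block) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept either an assembly BlockResult or a parsed stanza dict."""
    if isinstance(block, dict):
        return block["positions"], block["h1"].alleles, block["h2"].alleles
    return block.positions, block.h1.alleles, block.h2.alleles


def haplotype_error_rate(
    pred_blocks: list,
    truth_positions: np.ndarray,
    truth_h1: Haplotype,
    truth_h2: Haplotype,
) -> EvalReport:
    """HE (%) of predicted block haplotypes against an unmasked truth pair.

    Every predicted position must occur in the truth; the pooled HE is the
    position-weighted mean over blocks (total mismatches / total evaluated).
    """
    t1, t2 = truth_h1.alleles, truth_h2.alleles
    if t1.size != truth_positions.size or t2.size != truth_positions.size:
        raise InvalidInputError("truth haplotypes must match truth positions")
    if (t1 == MASKED).any() or (t2 == MASKED).any():
        raise InvalidInputError("truth haplotypes must be unmasked")

    per_block = []
    total_mism = 0
    total_eval = 0
    total_masked = 0
    for block in pred_blocks:
        positions, p1, p2 = _block_arrays(block)
        idx = np.searchsorted(truth_positions, positions)
        if (idx >= truth_positions.size).any() or (
            truth_positions[np.clip(idx, 0, truth_positions.size - 1)] != positions
        ).any():
            raise InvalidInputError("predicted positions missing from truth")
        bt1, bt2 = t1[idx], t2[idx]
        het = bt1 != bt2

        def _mism(a, b):
            # pairing (pred1 vs a, pred2 vs b); count unmasked het mismatches
            m1 = het & (p1 != MASKED) & (p1 != a)
            m2 = het & (p2 != MASKED) & (p2 != b)
            return int(m1.sum() + m2.sum())

        mism = min(_mism(bt1, bt2), _mism(bt2, bt1))
        evaluated = int((het & (p1 != MASKED)).sum() + (het & (p2 != MASKED)).sum())
        masked = int((het & (p1 == MASKED)).sum() + (het & (p2 == MASKED)).sum())
        per_block.append(100.0 * mism / evaluated if evaluated else 0.0)
        total_mism += mism
        total_eval += evaluated
        total_masked += masked

    pooled = 100.0 * total_mism / total_eval if total_eval else 0.0
    return EvalReport(
        pooled_he=pooled,
        per_block_he=per_block,
        evaluated_positions=total_eval,
        mismatches=total_mism,
        masked_positions=total_masked,
    )


def block_agreement(a_blocks: list, b_blocks: list) -> float:
    """Percentage of (block, haplotype, position) triples on which two
    solutions agree, under the best per-block label assignment.

    Blocks are matched by their position sets; solutions over disjoint
    positions raise."""
    if len(a_blocks) != len(b_blocks):
        raise InvalidInputError("solutions have different numbers of blocks")
    equal = 0
    total = 0
    for a, b in zip(a_blocks, b_blocks):
        pos_a, a1, a2 = _block_arrays(a)
        pos_b, b1, b2 = _block_arrays(b)
        common, ia, ib = np.intersect1d(pos_a, pos_b, return_indices=True)
        if common.size == 0:
            raise InvalidInputError("blocks share no positions")
        a1, a2, b1, b2 = a1[ia], a2[ia], b1[ib], b2[ib]
        eq_id = int((a1 == b1).sum() + (a2 == b2).sum())
        eq_sw = int((a1 == b2).sum() + (a2 == b1).sum())
        equal += max(eq_id, eq_sw)
        total += 2 * common.size
    return 100.0 * equal / total


def abf_curve(stats: list[GARunStats]) -> np.ndarray:
    """Per-iteration mean of best fitness across runs; shorter runs are
    right-padded with their final value."""
    if not stats:
        raise InvalidInputError("no GA runs provided")
    curves = [np.asarray(s.best_fitness_per_iteration, dtype=np.float64) for s in stats]
    if any(c.size == 0 for c in curves):
        raise InvalidInputError("a run has an empty fitness trace")
    length = max(c.size for c in curves)
    padded = np.vstack(
        [np.concatenate([c, np.full(length - c.size, c[-1])]) for c in curves]
    )
    return padded.mean(axis=0)
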