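import numpy as np
import pytest

from gaphase.assembly import (
    SubSolution,
    assemble,
    compute_gamma,
    correct_homozygous_sites,
    detect_blocks,
    mask_ambiguous,
    orient_and_merge,
    solve_subproblem,
    split_block,
)
from gaphase.core import MASKED, MISSING, Partition, infer_haplotypes, wmec_cost
from gaphase.evaluate import haplotype_error_rate
from gaphase.ga import GAConfig
from gaphase.simulate import SimConfig, simulate_matrix
from .conftest import matrix_from_strings, planted_instance


class TestDetectBlocks:
    def test_two_blocks(self):
        m = matrix_from_strings(["01--", "-10-", "---1"])
        blocks = detect_blocks(m)
        assert len(blocks) == 2
        np.testing.assert_array_equal(blocks[0].column_indices, [0, 1, 2])
        np.testing.assert_array_equal(blocks[1].column_indices, [3])
        np.testing.assert_array_equal(blocks[0].read_indices, [0, 1])
        np.testing.assert_array_equal(blocks[1].read_indices, [2])

    def test_single_spanning_read(self):
        m = matrix_from_strings(["0101"])
        assert len(detect_blocks(m)) == 1

    def test_chain_connectivity(self):
        m = matrix_from_strings(["01--", "-10-", "--01"])
        blocks = detect_blocks(m)
        assert len(blocks) == 1
        np.testing.assert_array_equal(blocks[0].column_indices, [0, 1, 2, 3])

    def test_union_find_oracle(self, rng):
        # oracle: repeated boolean closure over the column adjacency matrix
        for _ in range(10):
            mat, _ = planted_instance(rng, m=8, n=10, error_rate=0.3)
            d = mat.defined
            adj = np.zeros((mat.n, mat.n), dtype=bool)
            for i in range(mat.m):
                cols = np.flatnonzero(d[i])
                adj[np.ix_(cols, cols)] = True
            np.fill_diagonal(adj, True)
            for _ in range(mat.n):
                adj = (adj.astype(int) @ adj.astype(int)) > 0
            expected = {frozenset(np.flatnonzero(row)) for row in adj}
            got = {frozenset(b.column_indices.tolist()) for b in detect_blocks(mat)}
            assert got == expected

    def test_blocks_partition_columns(self, rng):
        mat, _ = planted_instance(rng, m=12, n=10, error_rate=0.2)
        blocks = detect_blocks(mat)
        all_cols = np.concatenate([b.column_indices for b in blocks])
        assert sorted(all_cols.tolist()) == list(range(mat.n))
        all_reads = np.concatenate([b.read_indices for b in blocks])
        assert sorted(all_reads.tolist()) == list(range(mat.m))


class TestComputeGamma:
    def _block(self, mean_coverage):
        from gaphase.assembly import Block

        return Block(np.arange(3), np.arange(4), mean_coverage)

    def test_integer_mean(self):
        assert compute_gamma(self._block(4.0)) == 4

    def test_round_half_up(self):
        assert compute_gamma(self._block(3.5)) == 4

    def test_floor_guard(self):
        assert compute_gamma(self._block(1.0)) == 2


class TestSplitBlock:
    def _make(self, m, n=30):
        rng = np.random.default_rng(0)
        mat, _ = planted_instance(rng, m=m, n=n, error_rate=0.1)
        (block,) = [b for b in detect_blocks(mat) if b.read_indices.size == m] or [
            detect_blocks(mat)[0]
        ]
        return mat, block

    def test_pi_formula(self, rng):
        mat, _ = planted_instance(rng, m=100, n=40, error_rate=0.1)
        blocks = detect_blocks(mat)
        big = max(blocks, key=lambda b: b.read_indices.size)
        m = big.read_indices.size
        chunks = split_block(mat, big, 30)
        assert len(chunks) == m // 30 + (1 if (m % 30) >= 15 else 0)

    def test_equal_chunks(self, rng):
        mat, _ = planted_instance(rng, m=90, n=40, error_rate=0.1)
        blocks = detect_blocks(mat)
        big = max(blocks, key=lambda b: b.read_indices.size)
        gamma = big.read_indices.size // 3
        if big.read_indices.size % 3 == 0:
            chunks = split_block(mat, big, gamma)
            assert all(len(c) == gamma for c in chunks)

    def test_remainder_preserved(self, rng):
        mat, _ = planted_instance(rng, m=7, n=12, error_rate=0.1)
        blocks = detect_blocks(mat)
        big = max(blocks, key=lambda b: b.read_indices.size)
        chunks = split_block(mat, big, 3)
        total = sum(len(c) for c in chunks)
        assert total == big.read_indices.size
        joined = np.concatenate(chunks)
        assert len(set(joined.tolist())) == total

    def test_chunks_genomically_ordered(self, rng):
        mat, _ = planted_instance(rng, m=40, n=20, error_rate=0.1)
        big = max(detect_blocks(mat), key=lambda b: b.read_indices.size)
        chunks = split_block(mat, big, 10)
        lefts = [mat.read_spans[c][:, 0].min() for c in chunks]
        assert lefts == sorted(lefts)


class TestSolveSubproblem:
    def test_error_free_recovers_planted(self):
        # dense zero-noise instance: planted pair is the unique optimum
        cfg = SimConfig(n_snps=15, f_snps=100, cov=10, read_len=600, error_rate=0.0, seed=3)
        mat, pos, h1, h2, prov = simulate_matrix(cfg)
        sol = solve_subproblem(mat, np.arange(mat.m), GAConfig(seed=1))
        assert sol.cost == 0
        truth1 = h1.alleles[sol.columns]
        both_covered = (sol.part_coverage > 0).all(axis=0)
        direct = (sol.h1[both_covered] == truth1[both_covered]).all()
        swapped = (sol.h2[both_covered] == truth1[both_covered]).all()
        assert direct or swapped

    def test_single_read(self):
        mat = matrix_from_strings(["0101"])
        sol = solve_subproblem(mat, np.array([0]), GAConfig(seed=0))
        assert sol.cost == 0
        part = sol.assignment[0]
        own = sol.h1 if part == 1 else sol.h2
        np.testing.assert_array_equal(own, [0, 1, 0, 1])

    def test_restricts_to_covered_columns(self, rng):
        mat, _ = planted_instance(rng, m=12, n=10, error_rate=0.1)
        sol = solve_subproblem(mat, np.array([0, 1]), GAConfig(seed=0))
        covered = np.flatnonzero(mat.defined[[0, 1]].any(axis=0))
        np.testing.assert_array_equal(sol.columns, covered)


def _manual_subsolution(h1, h2, coverage=3):
    h1 = np.asarray(h1, dtype=np.int8)
    n = h1.size
    return SubSolution(
        columns=np.arange(n),
        h1=h1,
        h2=np.asarray(h2, dtype=np.int8),
        assignment=np.array([1, 2], dtype=np.int8),
        part_coverage=np.full((2, n), coverage),
        stats=None,
        cost=0,
        entries=None,
    )


class TestOrientAndMerge:
    def test_agreeing_overlap_concatenates(self):
        a = _manual_subsolution([0, 1, 0], [1, 0, 1])
        b = _manual_subsolution([1, 0, 0], [0, 1, 1])  # matches a on overlap {1,2}
        b.columns = np.array([1, 2, 3])
        hap, flips = orient_and_merge([a, b], np.arange(4))
        assert not flips[1].any()
        np.testing.assert_array_equal(hap[0], [0, 1, 0, 0])

    def test_swapped_overlap_detected(self):
        a = _manual_subsolution([0, 1, 0], [1, 0, 1])
        b = _manual_subsolution([0, 1, 1], [1, 0, 0])  # swap of a on overlap {1,2}
        b.columns = np.array([1, 2, 3])
        hap, flips = orient_and_merge([a, b], np.arange(4))
        assert flips[1].all()
        np.testing.assert_array_equal(hap[0], [0, 1, 0, 0])
        np.testing.assert_array_equal(hap[1], [1, 0, 1, 1])

    def test_error_free_merge_recovers_planted(self, rng):
        for _ in range(5):
            cfg = SimConfig(n_snps=60, f_snps=100, cov=12, read_len=600, error_rate=0.0, seed=int(rng.integers(10_000)))
            mat, pos, h1, h2, _ = simulate_matrix(cfg)
            res = assemble(mat, GAConfig(seed=0))
            rep = haplotype_error_rate(res.blocks, pos, h1, h2)
            assert rep.pooled_he == 0.0


class TestHomozygousCorrection:
    def test_all_ones_column(self):
        entries = matrix_from_strings(["11", "10", "11"]).entries
        hap = np.array([[0, 1], [1, 0]], dtype=np.int8)
        out = correct_homozygous_sites(hap, entries)
        assert out[0, 0] == 1 and out[1, 0] == 1

    def test_with_missing(self):
        entries = matrix_from_strings(["01", "-0", "01"]).entries
        hap = np.array([[1, 1], [1, 0]], dtype=np.int8)
        out = correct_homozygous_sites(hap, entries)
        assert out[0, 0] == 0 and out[1, 0] == 0

    def test_no_homozygous_disagreement_after_correction(self, rng):
        for _ in range(10):
            mat, _ = planted_instance(rng, m=10, n=8, error_rate=0.3)
            hap = rng.integers(0, 2, size=(2, mat.n)).astype(np.int8)
            out = correct_homozygous_sites(hap, mat.entries)
            for j in range(mat.n):
                col = mat.entries[:, j]
                defined = col[col != MISSING]
                if len(set(defined.tolist())) == 1:
                    assert out[0, j] == out[1, j] == defined[0]


class TestMaskAmbiguous:
    def test_single_part_coverage_masks_other(self):
        entries = matrix_from_strings(["01", "00", "0-"]).entries
        hap = np.array([[0, 1], [1, 0]], dtype=np.int8)
        out = mask_ambiguous(hap, entries, np.array([1, 1, 1], dtype=np.int8))
        assert (out[1] == MASKED).all()
        np.testing.assert_array_equal(out[0], [0, 1])

    def test_both_parts_covered_unmasked(self):
        entries = matrix_from_strings(["01", "10"]).entries
        hap = np.array([[0, 1], [1, 0]], dtype=np.int8)
        out = mask_ambiguous(hap, entries, np.array([1, 2], dtype=np.int8))
        assert (out != MASKED).all()


class TestAssemble:
    def test_worker_count_invariance(self):
        for seed in range(3):
            cfg = SimConfig(n_snps=100, f_snps=100, cov=8, read_len=600, error_rate=0.05, seed=seed)
            mat, *_ = simulate_matrix(cfg)
            r1 = assemble(mat, GAConfig(seed=seed), workers=1)
            r4 = assemble(mat, GAConfig(seed=seed), workers=4)
            assert r1.total_cost == r4.total_cost
            assert len(r1.blocks) == len(r4.blocks)
            for a, b in zip(r1.blocks, r4.blocks):
                assert a.h1 == b.h1 and a.h2 == b.h2
                np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_conflict_free_total_cost_zero(self):
        cfg = SimConfig(n_snps=80, f_snps=100, cov=12, read_len=600, error_rate=0.0, seed=9)
        mat, *_ = simulate_matrix(cfg)
        res = assemble(mat, GAConfig(seed=9))
        assert res.total_cost == 0

    def test_block_count_matches_detection(self, rng):
        cfg = SimConfig(n_snps=80, f_snps=200, cov=6, read_len=600, error_rate=0.02, seed=4)
        mat, *_ = simulate_matrix(cfg)
        res = assemble(mat, GAConfig(seed=4))
        assert res.n_blocks == len(detect_blocks(mat))

    def test_block_independence_under_read_permutation(self):
        m = matrix_from_strings(["011-----", "01------", "-11-----", "-----101", "-----10-", "------01"])
        res1 = assemble(m, GAConfig(seed=5))
        perm = matrix_from_strings(["-----101", "011-----", "------01", "01------", "-----10-", "-11-----"])
        res2 = assemble(perm, GAConfig(seed=5))
        assert [b.h1.to_string() for b in res1.blocks] == [b.h1.to_string() for b in res2.blocks]
        assert [b.h2.to_string() for b in res1.blocks] == [b.h2.to_string() for b in res2.blocks]

    def test_reported_cost_consistent(self, rng):
        cfg = SimConfig(n_snps=60, f_snps=100, cov=10, read_len=600, error_rate=0.05, seed=2)
        mat, *_ = simulate_matrix(cfg)
        res = assemble(mat, GAConfig(seed=2))
        total = 0
        for b in res.blocks:
            bsub, _ = mat.row_submatrix(b.read_indices)
            total += wmec_cost(bsub, Partition(b.assignment), b.h1, b.h2)
        assert total == res.total_cost
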