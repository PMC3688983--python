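"""Kernel engine: Gram matrices, the sparse count buffer, split/assemble."""

import numpy as np
import pytest

from profkernel import (
    Profile,
    SparseCountBuffer,
    TrieParams,
    assemble,
    brute_force_feature_vector,
    compute_kernel_matrix,
    compute_sub_matrix,
    flush_buffer,
    generate_synthetic_profiles,
    plan_jobs,
    profile_from_sequence,
    read_kernel_tsv,
    write_kernel_tsv,
)
from profkernel.kernel import KernelNormalizationError, KernelOverflowError


def brute_force_gram(profiles, params):
    """Independent oracle: pairwise dot products of brute-force feature maps."""
    vectors = [brute_force_feature_vector(p, params) for p in profiles]
    n = len(profiles)
    gram = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            gram[i, j] = sum(
                c * vectors[j].get(leaf, 0) for leaf, c in vectors[i].items()
            )
    return gram


class TestComputeKernelMatrix:
    def test_saturation_closed_form_single_profile(self, zero_profile):
        # every one of the 20^3 leaves holds both windows: K = 20^3 * (L-k+1)^2
        kernel = compute_kernel_matrix([zero_profile], TrieParams(3, 1.0))
        assert kernel.values.tolist() == [[32000]]

    def test_spectrum_degenerate_profiles_share_nothing(self):
        a = profile_from_sequence("ACD", 0, 100, id="a")
        b = profile_from_sequence("CDE", 0, 100, id="b")
        kernel = compute_kernel_matrix([a, b], TrieParams(3, 50.0))
        assert kernel.values.tolist() == [[1, 0], [0, 1]]

    def test_matches_brute_force_gram(self, random_profiles):
        profiles = random_profiles[:10]
        params = TrieParams(3, 6.0)
        kernel = compute_kernel_matrix(profiles, params)
        assert np.array_equal(kernel.values, brute_force_gram(profiles, params))

    def test_symmetric_integer_and_psd(self, random_profiles):
        kernel = compute_kernel_matrix(random_profiles[:10], TrieParams(2, 5.0))
        assert np.issubdtype(kernel.values.dtype, np.integer)
        assert np.array_equal(kernel.values, kernel.values.T)
        eigenvalues = np.linalg.eigvalsh(kernel.values.astype(np.float64))
        assert eigenvalues.min() >= -1e-8 * np.linalg.norm(kernel.values)

    @pytest.mark.parametrize("capacity", [1, 7, 1000, 10**9])
    def test_buffer_capacity_invariance(self, random_profiles, capacity):
        profiles = random_profiles[:8]
        params = TrieParams(2, 5.0)
        reference = compute_kernel_matrix(profiles, params)
        kernel = compute_kernel_matrix(profiles, params, buffer_capacity=capacity)
        assert np.array_equal(kernel.values, reference.values)

    def test_saturation_closed_form_multi_profile(self, random_profiles):
        profiles = random_profiles[:4]
        k = 2
        sigma = k * max(float(p.scores.max()) for p in profiles) + 1
        kernel = compute_kernel_matrix(profiles, TrieParams(k, sigma))
        windows = np.array([p.length - k + 1 for p in profiles])
        expected = 20**k * np.outer(windows, windows)
        assert np.array_equal(kernel.values, expected)

    def test_monotone_in_sigma(self, random_profiles):
        profiles = random_profiles[:6]
        small = compute_kernel_matrix(profiles, TrieParams(2, 2.0))
        large = compute_kernel_matrix(profiles, TrieParams(2, 6.0))
        assert np.all(small.values <= large.values)

    def test_normalized_unit_diagonal(self, random_profiles):
        profiles = random_profiles[:5]
        kernel = compute_kernel_matrix(profiles, TrieParams(2, 5.0), normalize=True)
        assert np.allclose(np.diag(kernel.values), 1.0)
        assert np.all(kernel.values <= 1.0 + 1e-12)

    def test_normalize_zero_diagonal_errors_with_ids(self):
        conserved = Profile("alive", np.zeros((4, 20)))
        barren = Profile("barren", np.full((4, 20), 9.0))
        with pytest.raises(KernelNormalizationError, match="barren"):
            compute_kernel_matrix([conserved, barren], TrieParams(2, 1.0), normalize=True)

    def test_overflow_guard(self):
        profile = Profile("big", np.zeros((16, 20)))
        with pytest.raises(KernelOverflowError):
            compute_kernel_matrix([profile], TrieParams(14, 1.0))

    def test_kernel_tsv_round_trip(self, tmp_path, random_profiles):
        kernel = compute_kernel_matrix(random_profiles[:4], TrieParams(2, 4.0))
        path = tmp_path / "kernel.tsv"
        write_kernel_tsv(kernel, path)
        back = read_kernel_tsv(path)
        assert back.ids == kernel.ids
        assert np.array_equal(back.values, kernel.values)


class TestFlushBuffer:
    def test_empty_buffer_is_noop(self):
        buffer = SparseCountBuffer(10, 3, 400)
        accumulator = np.zeros((3, 3), dtype=np.int64)
        flush_buffer(buffer, accumulator)
        assert np.all(accumulator == 0)

    def test_single_triplet_self_product(self):
        buffer = SparseCountBuffer(10, 2, 400)
        buffer.add_leaf(5, np.array([0]), np.array([3]))
        accumulator = np.zeros((2, 2), dtype=np.int64)
        flush_buffer(buffer, accumulator)
        assert accumulator.tolist() == [[9, 0], [0, 0]] and len(buffer) == 0

    def test_random_buffer_matches_naive_pairwise_update(self):
        # oracle: the original per-leaf double loop over same-leaf triplets
        rng = np.random.default_rng(8)
        n_profiles, n_leaves = 6, 40
        buffer = SparseCountBuffer(10**6, n_profiles, n_leaves)
        naive = np.zeros((n_profiles, n_profiles), dtype=np.int64)
        for leaf in range(n_leaves):
            present = rng.permutation(n_profiles)[: rng.integers(0, n_profiles + 1)]
            present = np.sort(present)
            if len(present) == 0:
                continue
            counts = rng.integers(1, 6, size=len(present))
            buffer.add_leaf(leaf, present, counts)
            for i, ci in zip(present, counts):
                for j, cj in zip(present, counts):
                    naive[i, j] += ci * cj
        accumulator = np.zeros((n_profiles, n_profiles), dtype=np.int64)
        flush_buffer(buffer, accumulator)
        assert np.array_equal(accumulator, naive)


class TestPlanJobs:
    def test_single_group(self):
        (job,) = plan_jobs(10, 1)
        assert job.a_range == job.b_range == (0, 10) and job.is_diagonal

    def test_ceil_floor_group_sizes(self):
        jobs = plan_jobs(10, 3)
        assert len(jobs) == 6
        diagonal = [j for j in jobs if j.is_diagonal]
        sizes = sorted(j.a_range[1] - j.a_range[0] for j in diagonal)
        assert sizes == [3, 3, 4]

    @pytest.mark.parametrize("m, n_groups", [(17, 4), (200, 20), (5, 5), (9, 2)])
    def test_exhaustive_pair_coverage(self, m, n_groups):
        covered = np.zeros((m, m), dtype=int)
        for job in plan_jobs(m, n_groups):
            a0, a1 = job.a_range
            b0, b1 = job.b_range
            for a in range(a0, a1):
                for b in range(b0, b1):
                    if job.is_diagonal and a > b:
                        continue
                    covered[min(a, b), max(a, b)] += 1
        upper = np.triu_indices(m)
        assert np.all(covered[upper] == 1)

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            plan_jobs(3, 4)


class TestSplitAssemble:
    def test_single_group_job_equals_monolithic(self, random_profiles):
        profiles = random_profiles[:6]
        params = TrieParams(2, 4.0)
        (job,) = plan_jobs(len(profiles), 1)
        block = compute_sub_matrix(profiles, job, params)
        kernel = compute_kernel_matrix(profiles, params)
        assert np.array_equal(block.values, kernel.values)

    @pytest.mark.parametrize("n_groups", [2, 3, 5])
    def test_assembled_equals_monolithic_exactly(self, n_groups):
        profiles = generate_synthetic_profiles(30, (15, 25), 0.5, seed=21)
        params = TrieParams(2, 4.5)
        monolithic = compute_kernel_matrix(profiles, params)
        blocks = [
            compute_sub_matrix(profiles, job, params)
            for job in plan_jobs(len(profiles), n_groups)
        ]
        assembled = assemble(blocks)
        assert assembled.ids == monolithic.ids
        assert np.array_equal(assembled.values, monolithic.values)

    def test_off_diagonal_blocks_sit_inside_monolithic(self, random_profiles):
        profiles = random_profiles[:9]
        params = TrieParams(2, 4.0)
        monolithic = compute_kernel_matrix(profiles, params)
        for job in plan_jobs(len(profiles), 3):
            block = compute_sub_matrix(profiles, job, params)
            a0, a1 = job.a_range
            b0, b1 = job.b_range
            assert np.array_equal(block.values, monolithic.values[a0:a1, b0:b1])

    def test_single_profile_diagonal_block_is_squared_norm(self, random_profiles):
        profile = random_profiles[0]
        params = TrieParams(2, 4.0)
        (job,) = plan_jobs(1, 1)
        block = compute_sub_matrix([profile], job, params)
        squared_norm = sum(
            c * c for c in brute_force_feature_vector(profile, params).values()
        )
        assert block.values.tolist() == [[squared_norm]]

    def test_missing_block_named_in_error(self, random_profiles):
        profiles = random_profiles[:9]
        params = TrieParams(2, 4.0)
        blocks = [
            compute_sub_matrix(profiles, job, params)
            for job in plan_jobs(len(profiles), 3)
        ]
        removed = blocks.pop(1)
        with pytest.raises(ValueError, match=removed.job.name):
            assemble(blocks)

    def test_duplicate_block_rejected(self, random_profiles):
        profiles = random_profiles[:6]
        blocks = [
            compute_sub_matrix(profiles, job, TrieParams(2, 4.0))
            for job in plan_jobs(len(profiles), 2)
        ]
        with pytest.raises(ValueError, match="duplicate"):
            assemble(blocks + [blocks[0]])
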