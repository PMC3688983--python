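"""Profile-kernel Gram matrices via the sparse count buffer, plus split computation.

The kernel value between two profiles is the dot product of their conserved
k-mer count vectors, ``K(p, q) = Phi(p) . Phi(q)``.  Rather than updating the
Gram matrix pairwise at every trie leaf, per-leaf counts are appended to a
coordinate-list buffer (triplets ``[profile row, leaf column, count]``); when
adding the next leaf's triplets would exceed the buffer capacity the buffer is
flushed by a sparse self-multiplication ``C^T C`` (here ``C C^T`` with rows =
profiles) added onto the accumulator — arithmetically identical to the
pairwise update, operationally one sparse matrix product.

For matrices too large for one process, the profile set is partitioned into
``n`` contiguous groups and each of the ``n(n+1)/2`` unordered group pairs
becomes an independent sub-matrix job; assembling the job outputs reproduces
the monolithic matrix bit-identically (all arithmetic is 64-bit integer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .alphabet import N_AMINO_ACIDS
from .profiles import Profile, _check_unique_ids
from .trie import TrieParams, _leaf_stream

__all__ = [
    "KernelMatrix",
    "SparseCountBuffer",
    "SubMatrixJob",
    "SubMatrixBlock",
    "compute_kernel_matrix",
    "flush_buffer",
    "plan_jobs",
    "compute_sub_matrix",
    "assemble",
]

DEFAULT_BUFFER_CAPACITY = 100_000


class KernelOverflowError(OverflowError):
    """Raised when kernel counts could exceed the 64-bit integer range."""


class KernelNormalizationError(ValueError):
    """Raised when cosine normalization meets a profile with no conserved k-mers."""


@dataclass
class KernelMatrix:
    """Symmetric Gram matrix of feature-space dot products plus profile ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("id count must match matrix dimension")


def write_kernel_tsv(kernel: KernelMatrix, path: str | Path) -> None:
    """Write a kernel matrix as TSV with a leading id row and id column.

    Integer matrices are written as integers, so split/assembled output is
    byte-identical to the monolithic output.
    """
    is_integer = np.issubdtype(kernel.values.dtype, np.integer)
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("id\t" + "\t".join(kernel.ids) + "\n")
        for pid, row in zip(kernel.ids, kernel.values):
            if is_integer:
                cells = (str(int(v)) for v in row)
            else:
                cells = (repr(float(v)) for v in row)
            handle.write(pid + "\t" + "\t".join(cells) + "\n")


def read_kernel_tsv(path: str | Path) -> KernelMatrix:
    """Read a kernel matrix written by :func:`write_kernel_tsv`."""
    with Path(path).open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        ids = header[1:]
        rows = []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    values = np.array(rows)
    if values.size and np.all(values == np.round(values)):
        values = values.astype(np.int64)
    return KernelMatrix(values=values, ids=ids)


class SparseCountBuffer:
    """Coordinate-list buffer of (profile row, leaf column, count) triplets.

    At most one triplet exists per (row, column) pair between flushes because
    the traversal visits each leaf exactly once.  ``add_leaf`` reports whether
    the caller should flush *before* adding, implementing the policy: flush
    when adding the next leaf's triplets would exceed capacity, and once more
    at the end of the traversal.  A single leaf wider than the whole capacity
    is admitted alone and flushed immediately.
    """

    def __init__(self, capacity: int, n_rows: int, n_cols: int) -> None:
        if capacity < 1:
            raise ValueError("buffer capacity must be >= 1")
        self.capacity = capacity
        self.n_rows = n_rows
        self.n_cols = n_cols
        self._rows: list[np.ndarray] = []
        self._cols: list[np.ndarray] = []
        self._vals: list[np.ndarray] = []
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def would_overflow(self, n_new: int) -> bool:
        return self._size > 0 and self._size + n_new > self.capacity

    def add_leaf(self, leaf_index: int, profile_rows: np.ndarray, counts: np.ndarray) -> None:
        self._rows.append(np.asarray(profile_rows, dtype=np.int64))
        self._cols.append(np.full(len(profile_rows), leaf_index, dtype=np.int64))
        self._vals.append(np.asarray(counts, dtype=np.int64))
        self._size += len(profile_rows)

    def drain(self) -> sp.csr_matrix:
        """Return the buffered triplets as a CSR counts matrix and empty the buffer."""
        if self._size == 0:
            return sp.csr_matrix((self.n_rows, self.n_cols), dtype=np.int64)
        matrix = sp.coo_matrix(
            (
                np.concatenate(self._vals),
                (np.concatenate(self._rows), np.concatenate(self._cols)),
            ),
            shape=(self.n_rows, self.n_cols),
            dtype=np.int64,
        ).tocsr()
        self._rows.clear()
        self._cols.clear()
        self._vals.clear()
        self._size = 0
        return matrix


def flush_buffer(buffer: SparseCountBuffer, accumulator: np.ndarray) -> None:
    """Flush: ``accumulator += C C^T`` over the buffered columns, then empty the buffer.

    Arithmetically identical to the per-leaf pairwise kernel update.
    """
    if len(buffer) == 0:
        return
    counts = buffer.drain()
    accumulator += (counts @ counts.T).toarray()


def _check_overflow(profiles: Sequence[Profile], params: TrieParams) -> None:
    max_windows = max(p.length for p in profiles) - params.k + 1
    bound = float(N_AMINO_ACIDS) ** params.k * float(max_windows) ** 2
    if bound >= 2**62:
        raise KernelOverflowError(
            f"kernel entries may reach ~{bound:.3g}, beyond the 64-bit integer range"
        )


def _normalize(values: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    diagonal = np.diag(values).astype(np.float64)
    zero = [ids[i] for i in np.nonzero(diagonal == 0)[0]]
    if zero:
        raise KernelNormalizationError(
            "cannot cosine-normalize: profiles with no conserved k-mers "
            f"(zero diagonal): {', '.join(zero)}"
        )
    scale = 1.0 / np.sqrt(diagonal)
    return values * scale[:, None] * scale[None, :]


def compute_kernel_matrix(
    profiles: Sequence[Profile],
    params: TrieParams,
    buffer_capacity: int = DEFAULT_BUFFER_CAPACITY,
    normalize: bool = False,
) -> KernelMatrix:
    """Compute the full Gram matrix ``K[i, j] = Phi(p_i) . Phi(p_j)``.

    The result is exact 64-bit integer arithmetic and independent of
    ``buffer_capacity``.  With ``normalize=True`` the cosine-normalized matrix
    ``K[i,j] / sqrt(K[i,i] K[j,j])`` is returned instead (floats); a profile
    with no conserved k-mers makes normalization fail loudly.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    _check_unique_ids(profiles)
    _check_overflow(profiles, params)
    n = len(profiles)
    accumulator = np.zeros((n, n), dtype=np.int64)
    buffer = SparseCountBuffer(buffer_capacity, n, N_AMINO_ACIDS**params.k)
    for leaf, indices, counts in _leaf_stream(profiles, params):
        if buffer.would_overflow(len(indices)):
            flush_buffer(buffer, accumulator)
        buffer.add_leaf(leaf, indices, counts)
        if len(buffer) > buffer.capacity:
            flush_buffer(buffer, accumulator)
    flush_buffer(buffer, accumulator)
    values: np.ndarray = accumulator
    if normalize:
        values = _normalize(values, [p.id for p in profiles])
    return KernelMatrix(values=values, ids=[p.id for p in profiles])


@dataclass(frozen=True)
class SubMatrixJob:
    """One unordered group pair of a split kernel computation.

    ``group_a`` and ``group_b`` are contiguous, half-open index ranges into
    the full profile list; ``a_index <= b_index`` always.
    """

    a_index: int
    b_index: int
    a_range: tuple[int, int]
    b_range: tuple[int, int]
    n_groups: int

    @property
    def is_diagonal(self) -> bool:
        return self.a_index == self.b_index

    @property
    def name(self) -> str:
        return f"block_{self.a_index}_{self.b_index}"


def plan_jobs(m: int, n_groups: int) -> list[SubMatrixJob]:
    """Partition ``m`` profiles into ``n_groups`` contiguous groups and list all group-pair jobs.

    Group sizes are ``ceil(m/n)`` or ``floor(m/n)`` (larger groups first);
    the ``n(n+1)/2`` jobs cover every unordered pair exactly once.
    """
    if not (1 <= n_groups <= m):
        raise ValueError(f"need 1 <= n_groups <= m, got n_groups={n_groups}, m={m}")
    base, extra = divmod(m, n_groups)
    boundaries = [0]
    for g in range(n_groups):
        boundaries.append(boundaries[-1] + base + (1 if g < extra else 0))
    ranges = [(boundaries[g], boundaries[g + 1]) for g in range(n_groups)]
    return [
        SubMatrixJob(a, b, ranges[a], ranges[b], n_groups)
        for a in range(n_groups)
        for b in range(a, n_groups)
    ]


@dataclass
class SubMatrixBlock:
    """The output of one sub-matrix job: a rectangular block plus its row/column ids."""

    job: SubMatrixJob
    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]


def compute_sub_matrix(
    profiles: Sequence[Profile],
    job: SubMatrixJob,
    params: TrieParams,
    buffer_capacity: int = DEFAULT_BUFFER_CAPACITY,
) -> SubMatrixBlock:
    """Compute one job's block ``K[a, b]`` for ``a`` in group A, ``b`` in group B.

    Only the two groups' profiles are traversed; an off-diagonal job computes
    only cross-group dot products, a diagonal job the full symmetric block.
    Jobs share no state, so they can run in independent processes.
    """
    a_start, a_stop = job.a_range
    b_start, b_stop = job.b_range
    if not (0 <= a_start < a_stop <= len(profiles) and 0 <= b_start < b_stop <= len(profiles)):
        raise ValueError(f"job {job.name} does not fit a profile set of size {len(profiles)}")
    group_a = list(profiles[a_start:a_stop])
    if job.is_diagonal:
        kernel = compute_kernel_matrix(group_a, params, buffer_capacity)
        return SubMatrixBlock(job, kernel.values, kernel.ids, list(kernel.ids))
    group_b = list(profiles[b_start:b_stop])
    union = group_a + group_b
    _check_unique_ids(union)
    _check_overflow(union, params)
    na, nb = len(group_a), len(group_b)
    accumulator = np.zeros((na, nb), dtype=np.int64)
    buffer = SparseCountBuffer(buffer_capacity, na + nb, N_AMINO_ACIDS**params.k)

    def flush_cross() -> None:
        if len(buffer) == 0:
            return
        counts = buffer.drain()
        accumulator[...] += (counts[:na] @ counts[na:].T).toarray()

    for leaf, indices, counts in _leaf_stream(union, params):
        if buffer.would_overflow(len(indices)):
            flush_cross()
        buffer.add_leaf(leaf, indices, counts)
        if len(buffer) > buffer.capacity:
            flush_cross()
    flush_cross()
    return SubMatrixBlock(
        job,
        accumulator,
        [p.id for p in group_a],
        [p.id for p in group_b],
    )


def assemble(blocks: Sequence[SubMatrixBlock]) -> KernelMatrix:
    """Join sub-matrix blocks back into the full symmetric kernel matrix.

    The blocks must cover every job of one plan exactly once; the result is
    bit-identical to the monolithic :func:`compute_kernel_matrix` output.
    """
    if not blocks:
        raise ValueError("no blocks to assemble")
    n_groups = blocks[0].job.n_groups
    m = max(b.job.b_range[1] for b in blocks)
    expected = {job.name: job for job in plan_jobs(m, n_groups)}
    seen: dict[str, SubMatrixBlock] = {}
    for block in blocks:
        name = block.job.name
        if name not in expected:
            raise ValueError(f"unexpected block {name} for plan m={m}, n_groups={n_groups}")
        if name in seen:
            raise ValueError(f"duplicate block {name}")
        seen[name] = block
    missing = sorted(set(expected) - set(seen))
    if missing:
        raise ValueError(f"missing blocks: {', '.join(missing)}")

    ids: list[str] = [""] * m
    values = np.zeros((m, m), dtype=np.int64)
    for block in seen.values():
        a0, a1 = block.job.a_range
        b0, b1 = block.job.b_range
        if block.values.shape != (a1 - a0, b1 - b0):
            raise ValueError(
                f"block {block.job.name} has shape {block.values.shape}, "
                f"expected {(a1 - a0, b1 - b0)}"
            )
        values[a0:a1, b0:b1] = block.values
        values[b0:b1, a0:a1] = block.values.T
        ids[a0:a1] = block.row_ids
        ids[b0:b1] = block.col_ids
    return KernelMatrix(values=values, ids=ids)
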