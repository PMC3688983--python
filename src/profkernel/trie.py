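"""Depth-first traversal of the 20-ary, depth-k k-mer trie with score pruning.

This is the shared engine under kernel computation, normal-vector extraction
and query scoring.  Every node of the trie corresponds to a k-mer prefix; a
*candidate* is a (profile, window position) pair whose cumulative substitution
score for the current prefix is still at or below the threshold sigma.
Because scores are sums of non-negative terms, prefix scores are
non-decreasing with depth, so a candidate whose prefix score exceeds sigma can
be pruned: it cannot survive at any leaf below.

The score extension and the sigma comparison over a node's candidate list are
whole-array numpy operations (one gather of the 20 next-letter score columns
per node), never per-candidate interpreted loops; this is the engine's
vectorization contract and what lets it handle ~10^5 candidates per node.

Leaves are visited in strictly increasing leaf-index order (lexicographic
k-mer order), which fixes all downstream column orders and floating-point
accumulation orders.

An optional *descent restriction* prunes, in addition, any subtree in which no
candidate from a designated profile subset (typically the queries of a
prediction batch) survives; leaf callbacks for such subtrees never fire.  This
changes the work done but never the counts reported for the restricted subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .alphabet import N_AMINO_ACIDS
from .profiles import Profile

__all__ = [
    "TrieParams",
    "LeafCounts",
    "traverse",
    "feature_vector",
    "brute_force_feature_vector",
]


class ProfileTooShortError(ValueError):
    """Raised when a profile is shorter than the k-mer length."""


@dataclass(frozen=True)
class TrieParams:
    """Kernel parameters: k-mer length ``k`` and substitution score threshold ``sigma``.

    A k-mer is conserved in a window iff its cumulative substitution score is
    ``<= sigma`` (ties count as conserved).
    """

    k: int
    sigma: float

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or self.k < 1:
            raise ValueError("k must be an integer >= 1")
        if self.k > 14:
            raise ValueError("k must be <= 14 so that 20^k leaf indices fit 64 bits")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be a finite real >= 0")


@dataclass
class LeafCounts:
    """Surviving-candidate counts of one trie leaf.

    ``counts`` maps profile index -> number of windows of that profile whose
    k-mer neighborhood contains this leaf's k-mer; profiles with zero count
    are absent.
    """

    leaf_index: int
    counts: dict[int, int]


def _leaf_stream(
    profiles: Sequence[Profile],
    params: TrieParams,
    restrict_descent_to: Iterable[int] | None = None,
) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield ``(leaf_index, profile_indices, counts)`` in increasing leaf order.

    The internal fast path: arrays instead of dicts.  ``profile_indices`` is
    sorted ascending and ``counts`` holds the matching positive counts.
    """
    k, sigma = params.k, params.sigma
    n = len(profiles)
    for p in profiles:
        if p.length < k:
            raise ProfileTooShortError(
                f"profile {p.id!r} has length {p.length} < k={k}"
            )

    lengths = np.array([p.length for p in profiles])
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    stacked = np.vstack([p.scores for p in profiles])  # (sum L, 20)

    n_windows = lengths - k + 1
    prof_idx = np.repeat(np.arange(n), n_windows)
    rows = np.concatenate(
        [offsets[i] + np.arange(n_windows[i]) for i in range(n)]
    )
    scores = np.zeros(rows.shape[0])

    restricted: np.ndarray | None = None
    if restrict_descent_to is not None:
        restricted = np.zeros(n, dtype=bool)
        restricted[np.fromiter(restrict_descent_to, dtype=np.int64)] = True

    # explicit DFS stack of (depth, leaf prefix, candidate arrays); children
    # are pushed in reverse letter order so leaves pop lexicographically
    stack: list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray]] = [
        (0, 0, prof_idx, rows, scores)
    ]
    while stack:
        depth, prefix, pi, rw, sc = stack.pop()
        if depth == k:
            counts = np.bincount(pi, minlength=n)
            nonzero = np.nonzero(counts)[0]
            yield prefix, nonzero, counts[nonzero]
            continue
        # extend every candidate by all 20 letters at once
        extended = sc[:, None] + stacked[rw + depth, :]
        surviving = extended <= sigma
        if restricted is not None:
            candidate_restricted = restricted[pi]
        for letter in range(N_AMINO_ACIDS - 1, -1, -1):
            mask = surviving[:, letter]
            if not mask.any():
                continue
            if restricted is not None and not (mask & candidate_restricted).any():
                continue
            stack.append(
                (
                    depth + 1,
                    prefix * N_AMINO_ACIDS + letter,
                    pi[mask],
                    rw[mask],
                    extended[mask, letter],
                )
            )


def traverse(
    profiles: Sequence[Profile],
    params: TrieParams,
    on_leaf: Callable[[LeafCounts], None],
    restrict_descent_to: Iterable[int] | None = None,
) -> None:
    """Run the trie traversal, invoking ``on_leaf`` once per populated leaf.

    ``on_leaf`` fires exactly once for every leaf with at least one surviving
    candidate, in strictly increasing ``leaf_index`` order.  With
    ``restrict_descent_to`` (a set of profile indices), subtrees in which no
    candidate of that subset survives are skipped entirely.
    """
    for leaf_index, indices, counts in _leaf_stream(profiles, params, restrict_descent_to):
        on_leaf(
            LeafCounts(
                leaf_index=int(leaf_index),
                counts={int(i): int(c) for i, c in zip(indices, counts)},
            )
        )


def feature_vector(profile: Profile, params: TrieParams) -> dict[int, int]:
    """Sparse feature map Phi(p): leaf index -> number of conserved k-mers.

    Entry ``j`` counts the windows of ``profile`` whose conserved-k-mer
    neighborhood contains the k-mer encoded by leaf ``j``; the profile kernel
    is the dot product of two such vectors.
    """
    return {
        int(leaf): int(counts[0])
        for leaf, _, counts in _leaf_stream([profile], params)
    }


def brute_force_feature_vector(profile: Profile, params: TrieParams) -> dict[int, int]:
    """Definitionally correct feature map, enumerating all 20^k k-mers per window.

    No trie, no pruning: for every window the scores of all 20^k k-mers are
    materialized by broadcasting and compared against sigma directly.  Used as
    the independent oracle for :func:`feature_vector` at test scale.
    """
    k, sigma = params.k, params.sigma
    if N_AMINO_ACIDS**k > 10**7:
        raise ValueError(f"20^{k} k-mers is too many for brute-force enumeration")
    if profile.length < k:
        raise ProfileTooShortError(
            f"profile {profile.id!r} has length {profile.length} < k={k}"
        )
    counts = np.zeros(N_AMINO_ACIDS**k, dtype=np.int64)
    for start in range(profile.length - k + 1):
        total = profile.scores[start]
        for depth in range(1, k):
            total = total[..., None] + profile.scores[start + depth]
        counts += (total.reshape(-1) <= sigma).astype(np.int64)
    return {int(j): int(c) for j, c in enumerate(counts) if c > 0}
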