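# Methods

## The kernel

Each protein is given as a profile `p`: an `L x 20` matrix of non-negative
substitution scores, one row per sequence position, columns in the fixed
lexicographic amino-acid order `A,C,D,...,Y`.  Lower scores mean stronger
conservation.  For k-mer length `k` and threshold `sigma >= 0`, a k-mer
`a` is conserved in window `i` iff `sum_d p[i+d-1, a_d] <= sigma`; the
feature map `Phi(p)` counts conserved windows per k-mer, and the kernel is
`K(p, q) = Phi(p) . Phi(q)`, an exact non-negative integer.

**Tie rule.** Equality with sigma counts as conserved (`<=`, not `<`).  The
boundary case is exercised explicitly in the tests; users porting thresholds
from other implementations should check which convention those use, as a
strict rule shifts every count at scores landing exactly on sigma.

**Column and leaf order.** Leaf index = base-20 encoding of the k-mer with
the first letter most significant.  This single convention fixes the profile
column order, the traversal order (leaves fire in strictly increasing index
order), the normal-matrix row order and every floating-point accumulation
order, making all outputs reproducible run to run.

## Trie traversal

The engine is an iterative depth-first traversal of the 20-ary depth-k trie
with an explicit stack of `(depth, prefix, candidate arrays)` frames.  A
candidate is a `(profile, window)` pair with its cumulative prefix score.
Scores are sums of non-negative terms, so prefix scores are non-decreasing in
depth; a candidate over sigma is pruned permanently — the justification for
pruning and an invariant asserted (via oracle equivalence) in tests.

Per node, the extension to all 20 children is one numpy gather
(`scores[window_rows + depth, :]`) plus one vectorized comparison; no
per-candidate Python loop touches the hot path.  Children are pushed in
reverse letter order so leaves pop lexicographically.

An optional *descent restriction* (used by the baseline predictor) abandons
any subtree where no candidate from a designated profile subset survives;
this changes work done, never the counts reported for the restricted subset,
which is asserted by comparing restricted and full traversals.

Profiles shorter than `k` are rejected by the engine with the profile id in
the message; the batch-level `apply` workflow instead skips short queries
with a warning and proceeds, so a genome-scale batch does not die on one
fragment.

## Sparse count buffer

At each populated leaf, per-profile counts are appended to a coordinate list
(triplets `row, leaf, count`).  The flush policy is precise: flush when
adding the *next* leaf's triplets would exceed the capacity, and once at the
end of the traversal; a single leaf wider than the capacity is admitted alone
and flushed immediately.  A leaf's triplets are never split across flushes —
the self-product `C Cᵀ` only forms same-column products, so splitting a
column would silently drop within-leaf cross terms.  Buffer capacity is a
memory/speed dial only; all kernel arithmetic is 64-bit integer, and results
are asserted identical for capacities 1, 7, 1000 and unbounded.  A bound
check (`20^k * max_windows^2 < 2^62`) rejects parameter combinations that
could overflow instead of wrapping.

## Split computation

`plan_jobs(m, n)` partitions the input order into `n` contiguous groups
(sizes `ceil(m/n)` or `floor(m/n)`, larger first — deterministic index
arithmetic, no hashing) and emits all `n(n+1)/2` unordered group pairs.  Each
job traverses only its two groups' profiles and computes either a full
symmetric diagonal block or a cross-group rectangular block.  Jobs share no
state, so the `blocks` workflow runs them in separate worker processes;
because the arithmetic is integer, assembly is bit-identical to the
monolithic matrix for any group count and any process count.

## Normal matrix and scoring

For binary SVMs trained in dual form on the kernel, the discriminant normal
`w_j = sum_i alpha_i y_i Phi(x_i)` is materialized explicitly.  One traversal
over the union of support profiles builds all columns at once: at each leaf
the count vector is multiplied with the dense `(supports x SVMs)` weight
matrix, producing one normal-matrix row.  Rows are accumulated in leaf order;
only rows with a nonzero entry are stored (the dense matrix has `20^k` rows —
the entire reason for leaf sparsity).  Biases live beside the matrix, not as
an extra feature row, keeping counts integer.

Scoring a query batch is then `Phi(queries) . W + b`, computed with the same
buffered-counts machinery (counts flushed as a sparse matrix and multiplied
against the normal matrix).  The reference route scores through the
queries-vs-supports kernel block instead.  The two routes are algebraically
identical; numerically they differ only by float summation order, and since
the feature space is integer counts the observed discrepancy at test scale is
~1e-15 relative, asserted under 1e-9 with identical class predictions.

## SVM training and multi-class scheme

Binary SVMs are trained with scikit-learn's `SVC(kernel="precomputed")`, one
per class against the rest (one-vs-rest).  Prediction ranks classes by raw
SVM score with deterministic alphabetical tie-breaking (ties are flagged);
no probability calibration is attempted — the scores are uncalibrated margin
distances, and the output reports the margin to the runner-up class instead.
The cost parameter `C` (default 1.0) is exposed.

Cosine normalization of the kernel is available behind a flag and OFF by
default, so raw shared-k-mer counts are the canonical output.  When enabled,
the classifier trains on `K / sqrt(diag diagᵀ)`, scales each support's
extraction weight by `1/|Phi(x_i)|`, and divides query scores by `|Phi(q)|`,
which reproduces the normalized-kernel dual expansion exactly (cross-checked
against `SVC.decision_function` in both modes).  Profiles with no conserved
k-mer make normalization fail loudly rather than divide by zero.

## Synthetic data generator

Real applications use PSI-BLAST/HHblits-style profiles; generating those is
out of scope, and the package instead ships a seeded generator used by all
tests.  Per position one uniformly drawn "true" residue scores in `[0, 1)`
and the other 19 score in `[1.5, 3.0) + 6 * conservation`, so `conservation`
in (0, 1] directly controls how many k-mer neighbors fall under a given
sigma (verified: mean neighborhood size strictly shrinks from conservation
0.1 to 1.0).  The labeled variant implants a distinct random class motif
(default length 12) at a random position of each member, giving class-mates
shared conserved k-mers over a class-independent background.

What the generator does *not* emulate: realistic substitution-score
distributions (BLOSUM-like correlations between chemically similar residues),
position-dependent conservation structure along real domains, homology between
classes, or alignment noise.  Passing tests therefore demonstrate the
*arithmetic* of the kernel, the invariances, and that the pipeline separates
classes whose signal is conserved-k-mer sharing — not classification accuracy
on real proteomes.

## Default parameters and problem sizes

| parameter | default | notes |
|---|---|---|
| `k` | 3 | 20^3 = 8000 leaves; published applications use k = 4-6 with sigma 6-11 |
| `sigma` | 7.5 | mid-range for the generator's score bands at k = 3 |
| `C` | 1.0 | SVC soft-margin cost |
| `buffer_capacity` | 100000 triplets | memory/speed only |
| `conservation` | 0.9 (labeled), 0.5 (unlabeled) | high separation for the classification task |

The test and acceptance workloads use 100 profiles of length 20-60 for the
enumeration-oracle grid (k <= 3 so the brute-force oracle stays exhaustive),
10-30 profiles for Gram-matrix properties, and a 3-class, 20-per-class task
(15 train / 5 held out per class, k = 3, sigma = 3.0) for the end-to-end run;
at these sizes the full suite completes in well under a minute while every
oracle remains an exact, independent computation.

## Known limitations

* Desk scale: in-memory matrices only, intended for up to a few thousand
  profiles; no disk-backed Gram storage.
* No SIMD intrinsics; vectorization is numpy whole-array operations.
* A single `(k, sigma)` per traversal; multi-parameter single-pass traversal
  is not implemented.
* The model folder format is this package's own, versioned; no compatibility
  with other profile-kernel binaries' undocumented formats is attempted.
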