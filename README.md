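# profkernel

Fast profile string kernel for multi-class protein classification.

Protein classes — families, fold-level structural relations, sub-cellular
localization — are often predicted with SVMs over sequence-profile kernels.
The profile string kernel represents each protein by its evolutionary profile:
an `L x 20` matrix of per-position substitution scores over the amino acids
(lower score = residue more strongly conserved).  A k-mer `a = a_1 ... a_k` is
*conserved* in the window starting at position `i` when its cumulative score
stays at or below a threshold sigma:

```
score(a, p, i) = sum_{d=1..k} p[i+d-1, a_d]  <=  sigma
```

The feature map `Phi(p)` is the `20^k`-dimensional integer vector counting,
per k-mer, how many windows of `p` conserve it, and the kernel is the dot
product `K(p, q) = Phi(p) . Phi(q)`.  Conserved k-mers are enumerated by a
depth-first traversal of the 20-ary, depth-k k-mer trie with cumulative-score
pruning (scores are non-negative, so a prefix over sigma can never recover).

On top of the kernel, the package implements the accelerations that make this
classifier practical at scale:

* **Sparse count buffer** — per-leaf counts accumulate as coordinate-list
  triplets and flush into the Gram matrix via one sparse self-multiplication
  `C Cᵀ`, arithmetically identical to the per-leaf pairwise update.
* **Split/parallel kernel computation** — the profile set is partitioned into
  `n` contiguous groups; each of the `n(n+1)/2` group pairs is an independent
  sub-matrix job, and assembling the blocks reproduces the monolithic matrix
  bit-identically.
* **Explicit SVM normals** — for a trained dual SVM,
  `w = sum_i alpha_i y_i Phi(x_i)` is materialized leaf-sparse; one traversal
  builds the *normal matrix* of many SVMs at once, and scoring a query batch
  reduces to a sparse matrix product `Phi(queries) . W + b` instead of kernel
  evaluations against every support vector.
* **Baseline support-vector scorer** — the reference route
  `s = sum_i alpha_i y_i K(x_i, q) + b` with a targets-vs-supports restricted
  traversal, kept as an internal arithmetic oracle for the normal route.
* **One-call workflow** — `profkernel create` trains a one-vs-rest
  precomputed-kernel SVM classifier and stores a ready-to-use model folder;
  `profkernel apply` scores new queries against it.

## Worked example

```python
import numpy as np
from profkernel import generate_labeled_profiles
from profkernel.classifier import ProfileKernelClassifier

profiles, labels = generate_labeled_profiles(n_classes=3, n_per_class=20, seed=42)
train = profiles[:15] + profiles[20:35] + profiles[40:55]
test  = profiles[15:20] + profiles[35:40] + profiles[55:60]

clf = ProfileKernelClassifier(k=3, sigma=3.0).fit(train, [labels[p.id] for p in train])
print(len(clf.support_profiles_), clf.normal_.entries.nnz)
# 45 4644                      <- support profiles; nonzero normal-matrix entries

pred = clf.predict(test)
print(np.mean(pred == np.array([labels[p.id] for p in test])))
# 1.0                          <- held-out top-1 accuracy on the synthetic task

scores = clf.predict_scores(test[:2])
for qid, row in zip(scores.query_ids, scores.values):
    print(qid, np.round(row, 3))
# class0_p015 [ 0.725 -0.882 -0.843]
# class0_p016 [ 0.719 -0.848 -0.87 ]
```

Each score row holds the three one-vs-rest SVM scores (scaled distances to
the class hyperplanes, columns in `classes_` order); the predicted class is
the argmax, and members of `class0` indeed score positive only on the first
SVM.  The same pipeline is available from the shell:

```sh
profkernel generate --classes 3 -n 20 --seed 42 --profiles prof.txt --labels lab.tsv
profkernel create  --profiles prof.txt --labels lab.tsv -k 3 --sigma 3 --model model/
profkernel apply   --model model/ --queries prof.txt --output predictions.tsv
profkernel kernel  --profiles prof.txt -k 3 --sigma 3 --output gram.tsv
profkernel blocks  --profiles prof.txt --groups 4 --processes 4 --blocks-dir blocks/
profkernel assemble --profiles prof.txt --groups 4 --blocks-dir blocks/ --output gram.tsv
```

## File formats

* **Profiles** (text, defined by this package): records of a header `>ID L`
  followed by `L` lines of 20 whitespace-separated non-negative scores in
  amino-acid order `A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y`; `#` comments
  ignored.  Plain FASTA can be converted to degenerate one-hot profiles
  (`profiles_from_fasta`).
* **Labels**: two-column TSV `id<TAB>class`, no header.
* **Model folder**: `params.json` (k, sigma, SVM names, classes),
  `normals.npz` (compressed sparse normal matrix), `biases.tsv`,
  `training_ids.txt`, `manifest.json` (stage timings and class counts).
* **Predictions**: TSV `query_id, predicted_class, score, second_class, margin`.

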