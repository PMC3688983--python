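"""One-vs-rest profile-kernel SVM classifier, scikit-learn estimator style.

``ProfileKernelClassifier`` composes the engine modules: it builds the Gram
matrix of the training profiles with the sparse-buffered trie traversal,
trains one precomputed-kernel binary SVM per class (one-vs-rest), extracts
all discriminant normal vectors in a single traversal over the union of
support profiles, and predicts new queries by multiplying their conserved
k-mer counts against the resulting normal matrix.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``decision_function``, ``get_params`` / ``set_params``, trailing-underscore
fitted attributes) except that ``X`` is a sequence of :class:`Profile`
objects rather than a numeric array.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .kernel import DEFAULT_BUFFER_CAPACITY, compute_kernel_matrix
from .normals import DualSVM, NormalMatrix, extract_normals, load_model, save_model
from .profiles import Profile
from .scoring import predict_classes, score_queries, score_queries_baseline
from .trie import TrieParams

__all__ = ["ProfileKernelClassifier"]


class ProfileKernelClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class protein classifier on the profile string kernel.

    Parameters
    ----------
    k:
        k-mer length; the feature space has 20^k dimensions.
    sigma:
        Substitution score threshold; a k-mer is conserved in a window iff its
        cumulative score is <= sigma.  Larger sigma admits more neighbors.
    C:
        SVM soft-margin cost, passed to the per-class binary SVMs.
    normalize:
        Train on the cosine-normalized Gram matrix and scale query features
        accordingly at prediction time.
    buffer_capacity:
        Sparse count-buffer size (triplets) used during traversals; affects
        memory/speed only, never results.

    Attributes
    ----------
    classes_ : ndarray of class names, sorted.
    svms_ : list of :class:`DualSVM`, one per class in ``classes_`` order.
    normal_ : :class:`NormalMatrix` used for fast prediction.
    support_profiles_ : union of support profiles across all binary SVMs.
    """

    def __init__(
        self,
        k: int = 3,
        sigma: float = 7.5,
        C: float = 1.0,
        normalize: bool = False,
        buffer_capacity: int = DEFAULT_BUFFER_CAPACITY,
    ) -> None:
        self.k = k
        self.sigma = sigma
        self.C = C
        self.normalize = normalize
        self.buffer_capacity = buffer_capacity

    def _params(self) -> TrieParams:
        return TrieParams(k=self.k, sigma=self.sigma)

    def fit(self, X: Sequence[Profile], y: Sequence[str]) -> "ProfileKernelClassifier":
        """Fit one-vs-rest SVMs on the profile kernel and extract their normals."""
        profiles = list(X)
        labels = np.asarray([str(label) for label in y])
        if len(profiles) != len(labels):
            raise ValueError("X and y must have the same length")
        classes, class_indices = np.unique(labels, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("training requires at least 2 distinct classes")
        params = self._params()

        kernel = compute_kernel_matrix(
            profiles, params, buffer_capacity=self.buffer_capacity
        )
        gram = kernel.values.astype(np.float64)
        norms = np.sqrt(np.diag(gram))
        if self.normalize:
            if np.any(norms == 0):
                bad = [profiles[i].id for i in np.nonzero(norms == 0)[0]]
                raise ValueError(
                    f"cannot normalize: profiles with no conserved k-mers: {', '.join(bad)}"
                )
            gram = gram / norms[:, None] / norms[None, :]

        svms: list[DualSVM] = []
        extraction_svms: list[DualSVM] = []
        for ci, class_name in enumerate(classes):
            y_binary = np.where(class_indices == ci, 1, -1)
            svc = SVC(kernel="precomputed", C=self.C)
            svc.fit(gram, y_binary)
            support = svc.support_
            weights = svc.dual_coef_[0].copy()
            bias = float(svc.intercept_[0])
            support_ids = [profiles[i].id for i in support]
            svms.append(DualSVM(str(class_name), support_ids, weights, bias))
            if self.normalize:
                # w = sum_i (alpha_i y_i / |Phi(x_i)|) Phi(x_i) reproduces the
                # normalized-kernel dual expansion up to the query-norm factor
                extraction_svms.append(
                    DualSVM(str(class_name), support_ids, weights / norms[support], bias)
                )
        if not self.normalize:
            extraction_svms = svms

        support_union = sorted({sid for svm in svms for sid in svm.support_ids})
        by_id = {p.id: p for p in profiles}
        self.support_profiles_ = [by_id[sid] for sid in support_union]
        self.classes_ = classes
        self.svms_ = svms
        self.normal_ = extract_normals(self.support_profiles_, extraction_svms, params)
        self.train_ids_ = [p.id for p in profiles]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "normal_"):
            raise AttributeError("this ProfileKernelClassifier instance is not fitted yet")

    def decision_function(self, X: Sequence[Profile]) -> np.ndarray:
        """One-vs-rest SVM scores, shape (n_queries, n_classes), via the normal matrix."""
        self._check_fitted()
        scores = score_queries(
            list(X),
            self.normal_,
            buffer_capacity=self.buffer_capacity,
            normalize_queries=self.normalize,
        )
        return scores.values

    def decision_function_baseline(self, X: Sequence[Profile]) -> np.ndarray:
        """Same scores via the support-vector expansion (reference route)."""
        self._check_fitted()
        if not hasattr(self, "svms_"):
            raise AttributeError("baseline scoring needs the in-memory fitted SVMs")
        scores = score_queries_baseline(
            list(X),
            self.support_profiles_,
            self.svms_,
            self._params(),
            buffer_capacity=self.buffer_capacity,
            normalize=self.normalize,
        )
        return scores.values

    def predict(self, X: Sequence[Profile]) -> np.ndarray:
        """Top-scoring class per query; exact ties break by class-name order."""
        self._check_fitted()
        queries = list(X)
        scores = score_queries(
            queries,
            self.normal_,
            buffer_capacity=self.buffer_capacity,
            normalize_queries=self.normalize,
        )
        predictions = predict_classes(scores, classes=list(self.normal_.svm_names))
        return np.asarray([p.predicted_class for p in predictions])

    def predict_scores(self, X: Sequence[Profile]):
        """Full :class:`ScoreMatrix` (ids and SVM names attached)."""
        self._check_fitted()
        return score_queries(
            list(X),
            self.normal_,
            buffer_capacity=self.buffer_capacity,
            normalize_queries=self.normalize,
        )

    def save(self, path: str | Path) -> None:
        """Persist the fitted model as a model folder (see :func:`save_model`)."""
        self._check_fitted()
        save_model(
            self.normal_,
            path,
            training_ids=getattr(self, "train_ids_", []),
            extra={
                "estimator": "ProfileKernelClassifier",
                "classes": [str(c) for c in self.classes_],
                "normalize": bool(self.normalize),
                "C": float(self.C),
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProfileKernelClassifier":
        """Reload a saved model; the result predicts but cannot be re-fit in place."""
        normal, extra = load_model(path)
        estimator = cls(
            k=normal.params.k,
            sigma=normal.params.sigma,
            C=float(extra.get("C", 1.0)),
            normalize=bool(extra.get("normalize", False)),
        )
        estimator.normal_ = normal
        estimator.classes_ = np.asarray(extra.get("classes", normal.svm_names))
        return estimator
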