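"""Explicit SVM normal vectors in k-mer feature space, and their persistence.

A dual-form SVM trained on the profile kernel scores a query ``p`` as
``s = sum_i alpha_i y_i K(x_i, p) + b``.  Because the profile kernel operates
in an explicit (if huge) feature space, the discriminant normal
``w = sum_i alpha_i y_i Phi(x_i)`` can be materialized, reducing scoring to a
single sparse dot product ``s = w . Phi(p) + b``.

One trie traversal over the union of all support profiles suffices to build
the normals of many SVMs at once: at every populated leaf the per-profile
counts are combined with the per-SVM dual weights, yielding one row of the
*normal matrix* (rows = the 20^k k-mer leaves, columns = binary SVMs).  Only
rows with at least one nonzero entry are stored: dense 20^k storage is what
makes these matrices balloon to tens of gigabytes at k = 6.

Rows are accumulated in leaf-index order, fixing the floating-point summation
order for run-to-run reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import scipy.sparse as sp

from .alphabet import N_AMINO_ACIDS
from .profiles import Profile
from .trie import TrieParams, _leaf_stream

__all__ = ["DualSVM", "NormalMatrix", "extract_normals", "save_model", "load_model"]

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised on corrupted or incompatible model folders."""


@dataclass
class DualSVM:
    """A trained binary SVM in dual form: support ids, weights ``alpha_i * y_i``, bias."""

    name: str
    support_ids: list[str]
    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1 or len(self.weights) != len(self.support_ids):
            raise ValueError(f"SVM {self.name!r}: one weight per support id required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"SVM {self.name!r}: weights must be finite")
        if not np.any(self.weights != 0):
            raise ValueError(f"SVM {self.name!r}: at least one nonzero weight required")


@dataclass
class NormalMatrix:
    """Leaf-indexed sparse matrix of SVM discriminant normals plus biases.

    ``entries`` is ``(20^k, n_svms)`` CSR with only populated k-mer rows
    stored; column ``j`` is the normal vector of ``svm_names[j]``.
    """

    entries: sp.csr_matrix
    biases: np.ndarray
    params: TrieParams
    svm_names: list[str]

    def __post_init__(self) -> None:
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if self.entries.shape != (N_AMINO_ACIDS**self.params.k, len(self.svm_names)):
            raise ValueError(
                f"normal matrix shape {self.entries.shape} inconsistent with "
                f"k={self.params.k} and {len(self.svm_names)} SVMs"
            )
        if len(self.biases) != len(self.svm_names):
            raise ValueError("one bias per SVM required")

    @property
    def n_svms(self) -> int:
        return len(self.svm_names)


def extract_normals(
    support_profiles: Sequence[Profile],
    svms: Sequence[DualSVM],
    params: TrieParams,
) -> NormalMatrix:
    """Build the normal matrix of many SVMs in a single trie traversal.

    ``support_profiles`` must contain every support id of every SVM (extra
    profiles are allowed and simply carry zero weight everywhere).  Column
    ``j`` of the result equals ``sum_i weights_j[i] * Phi(x_i)`` restricted to
    its nonzero leaves; an SVM whose normal comes out identically zero is
    rejected, since it could never discriminate anything.
    """
    if not svms:
        raise ValueError("need at least one SVM")
    id_to_row = {p.id: i for i, p in enumerate(support_profiles)}
    if len(id_to_row) != len(support_profiles):
        raise ValueError("support profile ids must be unique")
    n, s = len(support_profiles), len(svms)
    weight_matrix = np.zeros((n, s))
    for j, svm in enumerate(svms):
        for sid, w in zip(svm.support_ids, svm.weights):
            if sid not in id_to_row:
                raise ValueError(
                    f"SVM {svm.name!r}: support id {sid!r} not among the given profiles"
                )
            weight_matrix[id_to_row[sid], j] = w

    leaf_rows: list[int] = []
    row_values: list[np.ndarray] = []
    for leaf, indices, counts in _leaf_stream(support_profiles, params):
        row = counts @ weight_matrix[indices]
        if np.any(row != 0):
            leaf_rows.append(leaf)
            row_values.append(row)

    shape = (N_AMINO_ACIDS**params.k, s)
    if leaf_rows:
        dense = np.vstack(row_values)
        nz_local, nz_col = np.nonzero(dense)
        entries = sp.coo_matrix(
            (dense[nz_local, nz_col], (np.asarray(leaf_rows)[nz_local], nz_col)),
            shape=shape,
        ).tocsr()
    else:
        entries = sp.csr_matrix(shape)
    column_nnz = entries.getnnz(axis=0)
    dead = [svms[j].name for j in np.nonzero(column_nnz == 0)[0]]
    if dead:
        raise ValueError(f"all-zero normal vector(s) for SVM(s): {', '.join(dead)}")
    return NormalMatrix(
        entries=entries,
        biases=np.array([svm.bias for svm in svms]),
        params=params,
        svm_names=[svm.name for svm in svms],
    )


def save_model(
    normal: NormalMatrix,
    path: str | Path,
    training_ids: Sequence[str] = (),
    extra: dict[str, Any] | None = None,
) -> None:
    """Persist a normal matrix as a model folder.

    Layout: ``params.json`` (format version, k, sigma, SVM names, any extras),
    ``normals.npz`` (compressed sparse archive), ``biases.tsv`` and
    ``training_ids.txt``.  ``load_model`` reproduces the matrix bit-exactly.
    """
    if normal.entries.getnnz() == 0:
        raise ValueError("refusing to save a normal matrix with no nonzero entries")
    folder = Path(path)
    folder.mkdir(parents=True, exist_ok=True)
    params: dict[str, Any] = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": normal.params.k,
        "sigma": normal.params.sigma,
        "svm_names": list(normal.svm_names),
    }
    if extra:
        params["extra"] = extra
    (folder / "params.json").write_text(json.dumps(params, indent=2) + "\n", encoding="utf-8")
    sp.save_npz(folder / "normals.npz", normal.entries.tocoo(), compressed=True)
    with (folder / "biases.tsv").open("w", encoding="utf-8", newline="\n") as handle:
        for name, bias in zip(normal.svm_names, normal.biases):
            handle.write(f"{name}\t{float(bias)!r}\n")
    (folder / "training_ids.txt").write_text(
        "".join(f"{tid}\n" for tid in training_ids), encoding="utf-8"
    )


def load_model(path: str | Path) -> tuple[NormalMatrix, dict[str, Any]]:
    """Load a model folder written by :func:`save_model`.

    Returns the normal matrix and the ``extra`` parameter dict (empty if none
    was stored).  Version mismatches and corrupted folders raise
    :class:`ModelFormatError`.
    """
    folder = Path(path)
    params_file = folder / "params.json"
    if not params_file.exists():
        raise ModelFormatError(f"{folder} is not a model folder (missing params.json)")
    try:
        params = json.loads(params_file.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupted params.json in {folder}: {exc}") from exc
    version = params.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {version} unsupported (expected {MODEL_FORMAT_VERSION})"
        )
    trie_params = TrieParams(k=int(params["k"]), sigma=float(params["sigma"]))
    svm_names = list(params["svm_names"])
    try:
        entries = sp.load_npz(folder / "normals.npz").tocsr()
    except (OSError, ValueError) as exc:
        raise ModelFormatError(f"corrupted or missing normals.npz in {folder}: {exc}") from exc
    biases = np.full(len(svm_names), np.nan)
    name_to_col = {name: j for j, name in enumerate(svm_names)}
    with (folder / "biases.tsv").open("r", encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            name, value = line.rstrip("\n").split("\t")
            if name not in name_to_col:
                raise ModelFormatError(f"bias for unknown SVM {name!r} in {folder}")
            biases[name_to_col[name]] = float(value)
    if np.any(np.isnan(biases)):
        raise ModelFormatError(f"missing bias entries in {folder}")
    normal = NormalMatrix(
        entries=entries, biases=biases, params=trie_params, svm_names=svm_names
    )
    return normal, params.get("extra", {})
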