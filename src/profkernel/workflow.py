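"""Single-call model creation and application pipeline.

Wraps the library modules into the five operating modes exposed by the CLI:

* ``kernel``   — compute the full Gram matrix of a profile set and write it as TSV.
* ``blocks``   — split the Gram computation into group-pair sub-matrix jobs and
  run them across worker processes, writing one ``block_<a>_<b>.tsv`` each.
* ``assemble`` — join block files back into the full matrix (byte-identical to
  ``kernel`` mode output).
* ``create``   — train a one-vs-rest profile-kernel SVM classifier from labeled
  profiles and store it as a ready-to-use model folder.
* ``apply``    — score query profiles with a stored model and write ranked
  class predictions.
"""

from __future__ import annotations

import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import ProfileKernelClassifier
from .kernel import (
    DEFAULT_BUFFER_CAPACITY,
    KernelMatrix,
    SubMatrixBlock,
    compute_kernel_matrix,
    compute_sub_matrix,
    assemble as assemble_blocks,
    plan_jobs,
    read_kernel_tsv,
    write_kernel_tsv,
)
from .profiles import Profile, read_labels, read_profiles
from .scoring import predict_classes
from .trie import TrieParams

logger = logging.getLogger("profkernel")

__all__ = ["RunConfig", "run_kernel", "run_blocks", "run_assemble", "run_create", "run_apply"]


@dataclass
class RunConfig:
    """Bag of pipeline settings shared by all modes; unused fields are ignored."""

    k: int = 3
    sigma: float = 7.5
    n_groups: int = 1
    n_processes: int = 1
    buffer_capacity: int = DEFAULT_BUFFER_CAPACITY
    normalize: bool = False
    svm_cost: float = 1.0
    profiles: Path | None = None
    labels: Path | None = None
    model: Path | None = None
    output: Path | None = None
    queries: Path | None = None
    blocks_dir: Path | None = None
    seed: int = 0

    def params(self) -> TrieParams:
        return TrieParams(k=self.k, sigma=self.sigma)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing required path(s): {', '.join(missing)}")


def run_kernel(config: RunConfig) -> KernelMatrix:
    """Compute the monolithic kernel matrix and write it to ``config.output``."""
    config.require("profiles", "output")
    profiles = read_profiles(config.profiles)
    kernel = compute_kernel_matrix(
        profiles, config.params(), config.buffer_capacity, normalize=config.normalize
    )
    write_kernel_tsv(kernel, config.output)
    logger.info("kernel matrix %dx%d written to %s", len(kernel.ids), len(kernel.ids), config.output)
    return kernel


def _write_block_tsv(block: SubMatrixBlock, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("id\t" + "\t".join(block.col_ids) + "\n")
        for rid, row in zip(block.row_ids, block.values):
            handle.write(rid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _read_block_tsv(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    with path.open("r", encoding="utf-8") as handle:
        col_ids = handle.readline().rstrip("\n").split("\t")[1:]
        row_ids: list[str] = []
        rows: list[list[int]] = []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    return np.array(rows, dtype=np.int64).reshape(len(row_ids), len(col_ids)), row_ids, col_ids


def _block_worker(
    profiles_path: str, job_index: int, m: int, n_groups: int,
    k: int, sigma: float, buffer_capacity: int, out_dir: str,
) -> str:
    """Compute one sub-matrix job in a worker process and write its block file."""
    profiles = read_profiles(profiles_path)
    job = plan_jobs(m, n_groups)[job_index]
    block = compute_sub_matrix(profiles, job, TrieParams(k=k, sigma=sigma), buffer_capacity)
    path = Path(out_dir) / f"{job.name}.tsv"
    _write_block_tsv(block, path)
    return str(path)


def run_blocks(config: RunConfig) -> list[Path]:
    """Run all sub-matrix jobs across ``n_processes`` workers, writing block files."""
    config.require("profiles", "blocks_dir")
    profiles = read_profiles(config.profiles)
    m = len(profiles)
    jobs = plan_jobs(m, config.n_groups)
    out_dir = Path(config.blocks_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    args = [
        (str(config.profiles), i, m, config.n_groups, config.k, config.sigma,
         config.buffer_capacity, str(out_dir))
        for i in range(len(jobs))
    ]
    if config.n_processes <= 1:
        paths = [_block_worker(*a) for a in args]
    else:
        with ProcessPoolExecutor(max_workers=config.n_processes) as pool:
            paths = list(pool.map(_block_worker, *zip(*args)))
    logger.info("wrote %d block files to %s", len(paths), out_dir)
    return [Path(p) for p in paths]


def run_assemble(config: RunConfig) -> KernelMatrix:
    """Join block files into the full kernel matrix and write it to ``config.output``."""
    config.require("profiles", "blocks_dir", "output")
    profiles = read_profiles(config.profiles)
    jobs = plan_jobs(len(profiles), config.n_groups)
    blocks: list[SubMatrixBlock] = []
    for job in jobs:
        path = Path(config.blocks_dir) / f"{job.name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing block file {job.name} (expected {path})")
        values, row_ids, col_ids = _read_block_tsv(path)
        blocks.append(SubMatrixBlock(job, values, row_ids, col_ids))
    kernel = assemble_blocks(blocks)
    write_kernel_tsv(kernel, config.output)
    return kernel


def run_create(config: RunConfig) -> ProfileKernelClassifier:
    """Train a classifier from labeled profiles and store it as a model folder.

    The model folder additionally receives a ``manifest.json`` logging the
    kernel parameters, class composition, SVM count and per-stage wall times.
    """
    config.require("profiles", "labels", "model")
    t0 = time.perf_counter()
    profiles = read_profiles(config.profiles)
    labels = read_labels(config.labels)
    known = {p.id for p in profiles}
    orphans = sorted(set(labels) - known)
    if orphans:
        raise ValueError(f"label file references missing profile id(s): {', '.join(orphans)}")
    unlabeled = sorted(known - set(labels))
    if unlabeled:
        raise ValueError(f"profile(s) without a label: {', '.join(unlabeled)}")
    y = [labels[p.id] for p in profiles]
    t_load = time.perf_counter()

    estimator = ProfileKernelClassifier(
        k=config.k,
        sigma=config.sigma,
        C=config.svm_cost,
        normalize=config.normalize,
        buffer_capacity=config.buffer_capacity,
    )
    estimator.fit(profiles, y)
    t_fit = time.perf_counter()

    estimator.save(config.model)
    t_save = time.perf_counter()

    class_counts = {c: y.count(c) for c in sorted(set(y))}
    manifest = {
        "k": config.k,
        "sigma": config.sigma,
        "normalize": config.normalize,
        "svm_cost": config.svm_cost,
        "n_profiles": len(profiles),
        "class_counts": class_counts,
        "n_svms": len(estimator.svms_),
        "n_support_profiles": len(estimator.support_profiles_),
        "stage_seconds": {
            "load": round(t_load - t0, 6),
            "fit": round(t_fit - t_load, 6),
            "save": round(t_save - t_fit, 6),
        },
    }
    (Path(config.model) / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    logger.info(
        "model with %d SVMs over %d classes written to %s",
        manifest["n_svms"], len(class_counts), config.model,
    )
    return estimator


def run_apply(config: RunConfig) -> Path:
    """Score query profiles with a stored model and write ranked predictions.

    Output TSV columns: query id, predicted class, its score, runner-up class
    and the score margin (6 decimals).  Queries shorter than k are skipped
    with a warning while the rest of the batch proceeds; an empty or fully
    skipped batch is an error.
    """
    config.require("model", "queries", "output")
    estimator = ProfileKernelClassifier.load(config.model)
    queries = read_profiles(config.queries)
    if not queries:
        raise ValueError(f"query file {config.queries} contains no profiles")
    k = estimator.k
    valid = [q for q in queries if q.length >= k]
    for q in queries:
        if q.length < k:
            logger.warning("skipping query %s: length %d < k=%d", q.id, q.length, k)
    if not valid:
        raise ValueError(f"no query is long enough for k={k}")
    scores = estimator.predict_scores(valid)
    predictions = predict_classes(scores, classes=list(estimator.classes_))
    out = Path(config.output)
    with out.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("query_id\tpredicted_class\tscore\tsecond_class\tmargin\n")
        for p in predictions:
            second = p.ranking[1][0] if len(p.ranking) > 1 else ""
            margin = p.margin if np.isfinite(p.margin) else 0.0
            handle.write(
                f"{p.query_id}\t{p.predicted_class}\t{p.ranking[0][1]:.6f}"
                f"\t{second}\t{margin:.6f}\n"
            )
    logger.info("predictions for %d/%d queries written to %s", len(valid), len(queries), out)
    return out
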