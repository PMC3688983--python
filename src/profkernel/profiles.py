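"""Protein profiles: the position-specific substitution-score matrices the kernel consumes.

A :class:`Profile` holds, for one protein of length ``L``, an ``L x 20`` matrix
of non-negative substitution scores over the standard amino acids in the fixed
column order ``A,C,D,...,Y``.  Scores follow PSSM-neighborhood semantics: the
*lower* the score of amino acid ``a`` at position ``i``, the more strongly
``a`` is conserved there.  A k-mer is "conserved" in a window when the sum of
its per-position scores stays at or below the user threshold sigma.

This module provides the plain-text profile format (read/write), degenerate
one-hot profiles built from plain sequences, label-file I/O, and two synthetic
generators: unlabeled random profiles and a labeled multi-class task with
class-specific implanted motifs.  The generators are first-class, seeded and
deterministic; they define the study conditions used throughout the tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_TO_COLUMN, AMINO_ACIDS, N_AMINO_ACIDS


class ProfileFormatError(ValueError):
    """Raised when a profile or label file violates the documented text format."""


@dataclass
class Profile:
    """One protein profile: an id plus an ``L x 20`` matrix of substitution scores.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within a profile set.
    scores:
        ``(L, 20)`` array of finite, non-negative floats; row = sequence
        position, column = amino acid in ``A,C,D,...,Y`` order; lower score
        means the amino acid is more strongly conserved at that position.
    """

    id: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("profile id must be non-empty")
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.ndim != 2 or scores.shape[1] != N_AMINO_ACIDS:
            raise ValueError(
                f"profile {self.id!r}: scores must have shape (L, 20), got {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValueError(f"profile {self.id!r}: length must be >= 1")
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"profile {self.id!r}: scores must all be finite")
        if np.any(scores < 0):
            raise ValueError(f"profile {self.id!r}: scores must all be non-negative")
        self.scores = scores

    @property
    def length(self) -> int:
        """Number of residues L."""
        return self.scores.shape[0]


def _check_unique_ids(profiles: Sequence[Profile]) -> None:
    seen: set[str] = set()
    for p in profiles:
        if p.id in seen:
            raise ProfileFormatError(f"duplicate profile id {p.id!r}")
        seen.add(p.id)


def read_profiles(path: str | Path) -> list[Profile]:
    """Parse a profile text file into an ordered list of :class:`Profile`.

    Format: records of a header line ``>ID L`` followed by exactly ``L`` lines
    of 20 whitespace-separated decimal scores; ``#`` comment lines ignored;
    UTF-8 with LF line endings.  Errors name the offending line number.
    """
    path = Path(path)
    profiles: list[Profile] = []
    with path.open("r", encoding="utf-8") as handle:
        current_id: str | None = None
        expected_rows = 0
        rows: list[list[float]] = []
        header_line = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if current_id is not None and len(rows) != expected_rows:
                    raise ProfileFormatError(
                        f"line {lineno}: record {current_id!r} (line {header_line}) has "
                        f"{len(rows)} score rows, expected {expected_rows}"
                    )
                if current_id is not None:
                    profiles.append(Profile(current_id, np.array(rows)))
                parts = line[1:].split()
                if len(parts) != 2:
                    raise ProfileFormatError(
                        f"line {lineno}: header must be '>ID L', got {line!r}"
                    )
                current_id = parts[0]
                try:
                    expected_rows = int(parts[1])
                except ValueError:
                    raise ProfileFormatError(
                        f"line {lineno}: record length {parts[1]!r} is not an integer"
                    ) from None
                if expected_rows < 1:
                    raise ProfileFormatError(f"line {lineno}: record length must be >= 1")
                rows = []
                header_line = lineno
                continue
            if current_id is None:
                raise ProfileFormatError(f"line {lineno}: score row before any '>' header")
            fields = line.split()
            if len(fields) != N_AMINO_ACIDS:
                raise ProfileFormatError(
                    f"line {lineno}: expected 20 scores, got {len(fields)}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError:
                raise ProfileFormatError(f"line {lineno}: non-numeric score") from None
            if any(not np.isfinite(v) or v < 0 for v in values):
                raise ProfileFormatError(
                    f"line {lineno}: scores must be finite and non-negative"
                )
            if len(rows) >= expected_rows:
                raise ProfileFormatError(
                    f"line {lineno}: record {current_id!r} has more than "
                    f"{expected_rows} score rows"
                )
            rows.append(values)
        if current_id is not None:
            if len(rows) != expected_rows:
                raise ProfileFormatError(
                    f"end of file: record {current_id!r} (line {header_line}) has "
                    f"{len(rows)} score rows, expected {expected_rows}"
                )
            profiles.append(Profile(current_id, np.array(rows)))
    _check_unique_ids(profiles)
    return profiles


def write_profiles(profiles: Sequence[Profile], path: str | Path) -> None:
    """Write profiles in the text format read by :func:`read_profiles`.

    Scores are written with shortest round-tripping decimal representation, so
    ``read_profiles(write_profiles(...))`` reproduces every field bit-exactly
    and repeated writes are byte-identical.
    """
    _check_unique_ids(profiles)
    buffer = io.StringIO()
    for p in profiles:
        buffer.write(f">{p.id} {p.length}\n")
        for row in p.scores:
            buffer.write(" ".join(repr(float(v)) for v in row))
            buffer.write("\n")
    Path(path).write_text(buffer.getvalue(), encoding="utf-8", newline="\n")


def profile_from_sequence(
    sequence: str, match_score: float = 0.0, mismatch_score: float = 100.0, id: str = "seq"
) -> Profile:
    """Build a degenerate one-hot profile from a plain amino-acid sequence.

    Row ``i`` carries ``match_score`` in the column of ``sequence[i]`` and
    ``mismatch_score`` everywhere else.  With ``match_score=0`` and a sigma
    below ``mismatch_score``, the profile kernel degenerates to the exact
    k-mer spectrum kernel of the sequence.

    Non-standard residues (B, Z, X, U, ``*`` ...) are rejected: silently
    remapping them would change kernel values invisibly.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not (0 <= match_score < mismatch_score):
        raise ValueError("require 0 <= match_score < mismatch_score")
    scores = np.full((len(sequence), N_AMINO_ACIDS), float(mismatch_score))
    for i, letter in enumerate(sequence.upper()):
        column = AA_TO_COLUMN.get(letter)
        if column is None:
            raise ValueError(
                f"residue {letter!r} at position {i} is not a standard amino acid "
                f"({AMINO_ACIDS}); non-standard residues are rejected, not remapped"
            )
        scores[i, column] = match_score
    return Profile(id=id, scores=scores)


# Score bands of the synthetic generator.  Per position one "true" residue
# scores in [TRUE_LOW, TRUE_HIGH); the 19 others score in
# [OTHER_BASE, OTHER_BASE + OTHER_SPREAD) + OTHER_SCALE * conservation, so the
# gap between conserved and non-conserved residues grows with `conservation`
# and higher conservation yields fewer conserved k-mer neighbors at fixed
# (k, sigma).  The bands keep mid-range sigmas (a few units per k-mer letter)
# non-degenerate at k <= 3.
_TRUE_LOW, _TRUE_HIGH = 0.0, 1.0
_OTHER_BASE, _OTHER_SPREAD, _OTHER_SCALE = 1.5, 1.5, 6.0


def _random_profile_scores(
    rng: np.random.Generator, length: int, conservation: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (scores, true_residues) for one random profile."""
    true_residues = rng.integers(0, N_AMINO_ACIDS, size=length)
    scores = _OTHER_BASE + rng.uniform(0.0, _OTHER_SPREAD, size=(length, N_AMINO_ACIDS))
    scores += _OTHER_SCALE * conservation
    scores[np.arange(length), true_residues] = rng.uniform(
        _TRUE_LOW, _TRUE_HIGH, size=length
    )
    return scores, true_residues


def generate_synthetic_profiles(
    n: int,
    length_range: tuple[int, int] = (30, 60),
    conservation: float = 0.5,
    seed: int = 0,
    id_prefix: str = "synthetic",
) -> list[Profile]:
    """Generate ``n`` random synthetic profiles, deterministically for a fixed seed.

    Each position has one uniformly drawn "true" residue with a low score and
    19 alternatives with higher scores; ``conservation`` in (0, 1] widens the
    gap, so larger values produce fewer conserved k-mer neighbors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length_range {length_range}: need 1 <= Lmin <= Lmax")
    if not (0.0 < conservation <= 1.0):
        raise ValueError("conservation must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        scores, _ = _random_profile_scores(rng, length, conservation)
        profiles.append(Profile(id=f"{id_prefix}{i:04d}", scores=scores))
    return profiles


def generate_labeled_profiles(
    n_classes: int = 3,
    n_per_class: int = 20,
    length_range: tuple[int, int] = (40, 60),
    conservation: float = 0.9,
    motif_length: int = 12,
    seed: int = 0,
) -> tuple[list[Profile], dict[str, str]]:
    """Generate a multi-class synthetic task with class-specific implanted motifs.

    Every class is assigned a distinct random residue motif of ``motif_length``.
    Each member profile is a random background profile into which the class
    motif is implanted (its residues become the "true" low-scoring residues of
    a contiguous window at a random position), so members of a class share the
    motif's conserved k-mers while background k-mers are class-independent.

    Returns the profiles (class-blocked, deterministic order) and an
    ``id -> class`` label map.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    lo, hi = length_range
    if not (1 <= motif_length <= lo):
        raise ValueError("motif_length must fit the shortest profile")
    rng = np.random.default_rng(seed)
    motifs: list[np.ndarray] = []
    while len(motifs) < n_classes:
        motif = rng.integers(0, N_AMINO_ACIDS, size=motif_length)
        if not any(np.array_equal(motif, m) for m in motifs):
            motifs.append(motif)
    profiles: list[Profile] = []
    labels: dict[str, str] = {}
    for class_index, motif in enumerate(motifs):
        class_name = f"class{class_index}"
        for member in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            scores, true_residues = _random_profile_scores(rng, length, conservation)
            start = int(rng.integers(0, length - motif_length + 1))
            window = np.arange(start, start + motif_length)
            # re-draw the window rows so the motif residues become the low band
            scores[window] = _OTHER_BASE + rng.uniform(
                0.0, _OTHER_SPREAD, size=(motif_length, N_AMINO_ACIDS)
            )
            scores[window] += _OTHER_SCALE * conservation
            scores[window, motif] = rng.uniform(_TRUE_LOW, _TRUE_HIGH, size=motif_length)
            pid = f"{class_name}_p{member:03d}"
            profiles.append(Profile(id=pid, scores=scores))
            labels[pid] = class_name
    return profiles, labels


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>class`` label file (no header)."""
    labels: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ProfileFormatError(
                    f"line {lineno}: expected 'id<TAB>class', got {line!r}"
                )
            if parts[0] in labels:
                raise ProfileFormatError(f"line {lineno}: duplicate label for {parts[0]!r}")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    """Write an ``id<TAB>class`` label file in insertion order."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for pid, cls in labels.items():
            handle.write(f"{pid}\t{cls}\n")


def profiles_from_fasta(
    path: str | Path, match_score: float = 0.0, mismatch_score: float = 100.0
) -> list[Profile]:
    """Read a FASTA file and convert each record to a degenerate one-hot profile."""
    from Bio import SeqIO

    profiles = [
        profile_from_sequence(str(record.seq), match_score, mismatch_score, id=record.id)
        for record in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(profiles)
    return profiles
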