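"""The 20-letter amino-acid alphabet and k-mer <-> leaf-index codecs.

Leaf indices are the base-20 encoding of a k-mer in the fixed lexicographic
one-letter-code order ``A,C,D,...,Y``, with the first k-mer letter most
significant.  This ordering fixes the column order of every profile, the
depth-first traversal order of the k-mer trie and all downstream leaf-indexed
matrices, so it must never change.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AMINO_ACIDS: int = len(AMINO_ACIDS)

AA_TO_COLUMN: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def kmer_to_leaf_index(kmer: str) -> int:
    """Encode a k-mer string as its leaf index (base-20, first letter most significant)."""
    index = 0
    for letter in kmer:
        try:
            index = index * N_AMINO_ACIDS + AA_TO_COLUMN[letter]
        except KeyError:
            raise ValueError(
                f"{letter!r} is not one of the 20 standard amino acids ({AMINO_ACIDS})"
            ) from None
    return index


def leaf_index_to_kmer(index: int, k: int) -> str:
    """Decode a leaf index back to the k-mer string of length ``k``."""
    if not 0 <= index < N_AMINO_ACIDS**k:
        raise ValueError(f"leaf index {index} out of range for k={k}")
    letters = []
    for _ in range(k):
        index, remainder = divmod(index, N_AMINO_ACIDS)
        letters.append(AMINO_ACIDS[remainder])
    return "".join(reversed(letters))
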