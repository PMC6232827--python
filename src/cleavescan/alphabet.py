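"""Residue alphabet shared across the package.

The 20 standard amino acids in the fixed column order used by every
matrix in this package. Anything outside this alphabet (B, Z, X, U,
``*`` ...) is rejected by matrix builders and soft-skipped by the
proteome scanner.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES: int = len(AMINO_ACIDS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ResidueAlphabetError(ValueError):
    """A sequence contains a residue outside the 20 standard amino acids."""


def check_residue(aa: str) -> str:
    """Return ``aa`` if it is a standard residue, else raise."""
    if len(aa) != 1 or aa not in AA_INDEX:
        raise ResidueAlphabetError(f"non-standard residue {aa!r}")
    return aa


def check_sequence(seq: str) -> str:
    """Return ``seq`` if every residue is standard, else raise."""
    for aa in seq:
        if aa not in AA_INDEX:
            raise ResidueAlphabetError(
                f"non-standard residue {aa!r} in sequence {seq!r}"
            )
    return seq


def is_standard(seq: str) -> bool:
    return all(aa in AA_INDEX for aa in seq)


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as an int8 array of alphabet indices."""
    check_sequence(seq)
    return np.fromiter((AA_INDEX[aa] for aa in seq), dtype=np.int8, count=len(seq))


def decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[int(c)] for c in codes)
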