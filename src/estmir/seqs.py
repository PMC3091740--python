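"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

# integer encoding used by the scanner: U and T share a code, N is 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as uint8 with U==T and N=4."""
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid sequence character {exc.args[0]!r}") from None
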