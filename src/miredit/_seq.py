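"""Small sequence helpers shared across modules.

All genomic sequences are handled in the DNA alphabet internally; mature
miRNA sequences are exposed in the RNA alphabet at API boundaries.
"""

from __future__ import annotations

import numpy as np

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = set("ACGTUN")

# integer encoding used by the mapper / pileup fast paths
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_TO_BASE = "ACGTN"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_DNA_COMPLEMENT)


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def validate_alphabet(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(CODE_TO_BASE[c] for c in codes)
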