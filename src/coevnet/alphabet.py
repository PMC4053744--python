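"""Amino-acid alphabet and integer encoding shared by all modules.

The 20 standard residues are indexed 0..19 in the order below; the alignment
gap character ``-`` is index 20.  Sequences are stored as strings at module
boundaries and as ``int8`` arrays internally.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP

N_AA = 20
GAP_INDEX = 20
N_SYMBOLS = 21

SYMBOL_INDEX = {c: i for i, c in enumerate(ALPHABET)}

# lookup table for fast encoding; 255 marks an invalid character
_ENCODE_LUT = np.full(128, 255, dtype=np.uint8)
for _c, _i in SYMBOL_INDEX.items():
    _ENCODE_LUT[ord(_c)] = _i

_DECODE_LUT = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def validate_sequence(seq: str) -> None:
    """Raise ``ValueError`` if *seq* contains a character outside the alphabet."""
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"sequence contains characters outside the 20-AA+gap alphabet: {sorted(bad)!r}"
        )


def encode(seq: str) -> np.ndarray:
    """Encode an aligned sequence to an int8 array (gap -> 20)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENCODE_LUT[raw]
    if (out == 255).any():
        validate_sequence(seq)  # raises with a readable message
    return out.astype(np.int8)


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE_LUT[np.asarray(arr, dtype=np.intp)].tobytes().decode("ascii")
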