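"""Small sequence helpers shared across modules.

Everything operates on uppercase DNA strings; 'N' marks a masked base and
survives complementation unchanged.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level complement lookup for vectorised operations (identity elsewhere)
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b

# base -> code table used by the read simulator; non-ACGT maps to 255
BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    BASE_TO_CODE[_c] = _i
CODE_TO_BASE = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def complement_bytes(arr: np.ndarray) -> np.ndarray:
    """Complement an array of single-byte base characters."""
    return _COMP_TABLE[arr.view(np.uint8)].view(arr.dtype)


def to_rna(seq: str) -> str:
    """Transliterate a DNA string to RNA (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")


def seq_to_bytes(seq: str) -> np.ndarray:
    """View a sequence string as a numpy array of 1-byte characters."""
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def bytes_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")
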