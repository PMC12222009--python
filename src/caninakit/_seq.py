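"""Nucleotide encoding helpers shared across the package.

Sequences are held internally as ``numpy.uint8`` arrays with the code
A=0, C=1, G=2, T=3; strings only appear at I/O boundaries.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array (case-insensitive)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _DECODE[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (A<->T, C<->G)."""
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    if a.shape != b.shape:
        raise ValueError("hamming distance requires equal-length sequences")
    return int(np.count_nonzero(a != b))
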