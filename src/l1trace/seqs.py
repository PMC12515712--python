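"""Small DNA sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte value -> 2-bit code; A=0 C=1 G=2 T=3, anything else 4.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A0 C1 G2 T3, other 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 decodes to N)."""
    return _DEC[codes].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming: unequal lengths")
    return sum(x != y for x, y in zip(a, b))
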