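"""Small sequence helpers: 2-bit encoding, reverse complement, hashing."""
from __future__ import annotations

import numpy as np

# 2-bit base codes; 4 marks any character outside {A,C,G,T} (normalized to N).
A, C, G, T, N = 0, 1, 2, 3, 4

_ENC = np.full(256, N, dtype=np.uint8)
for _b, _c in zip(b"ACGT", (A, C, G, T)):
    _ENC[_b] = _c
    _ENC[ord(chr(_b).lower())] = _c

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def mix64(x: np.ndarray | int):
    """Invertible 64-bit integer finalizer (xor-shift/multiply chain).

    Invertibility guarantees that equal hashes imply equal k-mers, so every
    anchor derived from a hash match is an exact sequence match.
    """
    x = np.uint64(x) if np.isscalar(x) else x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(33)
        x *= np.uint64(0xFF51AFD7ED558CCD)
        x ^= x >> np.uint64(33)
        x *= np.uint64(0xC4CEB9FE1A85EC53)
        x ^= x >> np.uint64(33)
    return x
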