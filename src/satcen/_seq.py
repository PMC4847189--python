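"""Low-level nucleotide encoding helpers shared across modules.

Bases are encoded as integers A=0, C=1, G=2, T=3, N=4.  N never matches
anything (including another N), so it behaves as a guaranteed mismatch in
all identity computations.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGTN"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_CODE[ord("U")] = 3  # RNA alphabet folds onto T
_CODE[ord("u")] = 3

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of A,C,G,T is T,G,C,A; N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes; reject non-ACGTN symbols."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes < 0).any():
        bad = chr(int(raw[np.argmax(codes < 0)]))
        raise ValueError(f"sequence contains non-ACGTN symbol {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement codes along the last axis (batch-safe)."""
    return _COMP[codes[..., ::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def onehot(codes: np.ndarray, dtype=np.float32) -> np.ndarray:
    """One-hot encode (B, L) codes into (B, L, 4).

    N bases produce an all-zero row, i.e. they can never contribute a
    match.
    """
    codes = np.atleast_2d(codes)
    b, length = codes.shape
    out = np.zeros((b, length, 4), dtype=dtype)
    rows = np.repeat(np.arange(b), length)
    cols = np.tile(np.arange(length), b)
    flat = codes.ravel()
    keep = flat < 4
    out[rows[keep], cols[keep], flat[keep]] = 1.0
    return out
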