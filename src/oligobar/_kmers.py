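"""Nucleotide encoding and exact k-mer hashing shared by the probe-design modules.

Bases are coded A=0, C=1, G=2, T=3, N=4; any other character maps to 5 so
that invalid input is detectable and never silently matches anything.
k-mers are hashed as base-4 integers, which is collision-free for k <= 31
in int64 arithmetic (4**31 < 2**63).
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

# complement; N and invalid codes map to themselves
_COMP = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)
_BASES = np.frombuffer(b"ACGTN?", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 hashes of all k-windows of ``codes``.

    Returns ``(hashes, valid)`` where ``valid[i]`` is False for windows
    containing N or invalid characters (their hash value is meaningless).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = np.where(codes < 4, codes, 0).astype(np.int64)
    h = np.zeros(n, dtype=np.int64)
    for i in range(k):
        h = h * 4 + c[i : i + n]
    bad = np.concatenate(([0], np.cumsum((codes >= 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return h, valid


def kmer_hash(kmer: str) -> int:
    """Hash of a single k-mer; -1 if it contains non-ACGT characters."""
    codes = encode(kmer)
    if (codes >= 4).any():
        return -1
    h = 0
    for c in codes:
        h = h * 4 + int(c)
    return h
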