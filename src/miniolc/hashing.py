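"""64-bit k-mer hashing primitives shared by sketching and overlapping.

K-mers are packed into 64-bit integers (2 bits/base, k <= 32) and hashed
with a splitmix64-style finalizer under a fixed base seed, so the same
k-mer receives the same base hash everywhere in the pipeline. Per-slot
weighted-MinHash draws are derived deterministically from
(base hash, slot salt, draw index).
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

# Fixed base seed: k-mers must index identically across reads and stages.
BASE_HASH_SEED = np.uint64(0x9E3779B97F4A7C15)

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0 C=1 G=2 T=3); non-ACGT mapped to A."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    codes[codes == 255] = 0
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed forward-strand k-mer integers for every position (uint64)."""
    if not 1 <= k <= 32:
        raise ValueError("k must be in [1, 32]")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= c[j : j + n]
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-canonical packed k-mers: min(code, revcomp code) per position."""
    fwd = kmer_codes(codes, k)
    rc = kmer_codes(_COMP[codes][::-1], k)[::-1]
    return np.minimum(fwd, rc)


def splitmix64(x: np.ndarray, seed: np.uint64 = BASE_HASH_SEED) -> np.ndarray:
    """Vectorized splitmix64 finalizer over uint64 arrays."""
    with np.errstate(over="ignore"):
        z = (x + seed) * np.uint64(1)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z


def kmer_hashes(seq_codes: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """Base hashes of all k-mers of a sequence (canonical by default)."""
    km = canonical_kmer_codes(seq_codes, k) if canonical else kmer_codes(seq_codes, k)
    return splitmix64(km)


@njit(cache=True)
def _mix(z):
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(cache=True)
def weighted_minhash_kernel(hashes, weights, slot_salts):
    """Per-slot weighted MinHash.

    For slot i with salt t_i, k-mer with base hash h and integer weight w
    receives draws v_j = mix(h ^ t_i ^ j*GOLDEN) for j in [0, w); the slot
    stores the base hash of the k-mer attaining the minimum draw. Draw j
    depends only on (h, slot, j), so reads sharing a k-mer share its draws
    up to the smaller of their two weights.
    """
    s = slot_salts.shape[0]
    n = hashes.shape[0]
    out = np.empty(s, dtype=np.uint64)
    golden = uint64(0x9E3779B97F4A7C15)
    for i in range(s):
        salt = slot_salts[i]
        best = uint64(0xFFFFFFFFFFFFFFFF)
        best_h = uint64(0)
        for a in range(n):
            h = hashes[a]
            w = weights[a]
            hx = h ^ salt
            for j in range(w):
                v = _mix(hx ^ (uint64(j) * golden))
                if v < best:
                    best = v
                    best_h = h
        out[i] = best_h
    return out


def slot_salts(s: int, seed: int) -> np.ndarray:
    """Deterministic per-slot salts derived from a sketch seed."""
    idx = np.arange(1, s + 1, dtype=np.uint64)
    with np.errstate(over="ignore"):
        mixed = idx * _GOLDEN + np.uint64(seed) * np.uint64(0xD6E8FEB86659FD93)
    return splitmix64(mixed)
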