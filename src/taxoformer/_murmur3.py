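"""MurmurHash3 x64-128 for k-mer hashing.

The hashing-based tokenization schemes (LSH bucketing and hash embeddings)
require a fast, seedable, platform-stable non-cryptographic hash.  This module
implements the x64_128 variant of MurmurHash3 (Austin Appleby's reference
algorithm): a scalar version for arbitrary byte strings and a vectorised
NumPy version for batches of equal-length keys of at most 15 bytes (the
tail-only case), which covers every k-mer length the tokenizers use after
position subsampling.

Outputs are bit-identical between the two paths and match the reference C++
implementation (see the frozen test vectors in the test suite).
"""

from __future__ import annotations

import numpy as np

_MASK64 = (1 << 64) - 1
_C1 = 0x87C37B91114253D5
_C2 = 0x4CF5AD432745937F


def _rotl64(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _MASK64


def _fmix64(k: int) -> int:
    k ^= k >> 33
    k = (k * 0xFF51AFD7ED558CCD) & _MASK64
    k ^= k >> 33
    k = (k * 0xC4CEB9FE1A85EC53) & _MASK64
    k ^= k >> 33
    return k


def murmur3_x64_128(key: bytes, seed: int = 0) -> int:
    """Hash *key*, returning the 128-bit digest as an int (h1 = low 64 bits)."""
    length = len(key)
    nblocks = length // 16
    h1 = seed & _MASK64
    h2 = seed & _MASK64

    for i in range(nblocks):
        k1 = int.from_bytes(key[i * 16 : i * 16 + 8], "little")
        k2 = int.from_bytes(key[i * 16 + 8 : i * 16 + 16], "little")

        k1 = (k1 * _C1) & _MASK64
        k1 = _rotl64(k1, 31)
        k1 = (k1 * _C2) & _MASK64
        h1 ^= k1

        h1 = _rotl64(h1, 27)
        h1 = (h1 + h2) & _MASK64
        h1 = (h1 * 5 + 0x52DCE729) & _MASK64

        k2 = (k2 * _C2) & _MASK64
        k2 = _rotl64(k2, 33)
        k2 = (k2 * _C1) & _MASK64
        h2 ^= k2

        h2 = _rotl64(h2, 31)
        h2 = (h2 + h1) & _MASK64
        h2 = (h2 * 5 + 0x38495AB5) & _MASK64

    tail = key[nblocks * 16 :]
    k1 = 0
    k2 = 0
    tlen = len(tail)
    if tlen >= 9:
        for i in range(tlen - 1, 7, -1):
            k2 ^= tail[i] << ((i - 8) * 8)
        k2 = (k2 * _C2) & _MASK64
        k2 = _rotl64(k2, 33)
        k2 = (k2 * _C1) & _MASK64
        h2 ^= k2
    if tlen >= 1:
        for i in range(min(tlen, 8) - 1, -1, -1):
            k1 ^= tail[i] << (i * 8)
        k1 = (k1 * _C1) & _MASK64
        k1 = _rotl64(k1, 31)
        k1 = (k1 * _C2) & _MASK64
        h1 ^= k1

    h1 ^= length
    h2 ^= length
    h1 = (h1 + h2) & _MASK64
    h2 = (h2 + h1) & _MASK64
    h1 = _fmix64(h1)
    h2 = _fmix64(h2)
    h1 = (h1 + h2) & _MASK64
    h2 = (h2 + h1) & _MASK64
    return (h2 << 64) | h1


def murmur3_low64(key: bytes, seed: int = 0) -> int:
    """Low 64 bits (h1) of the x64_128 digest — the hash the tokenizers use."""
    return murmur3_x64_128(key, seed) & _MASK64


def _rotl64_np(x: np.ndarray, r: int) -> np.ndarray:
    return (x << np.uint64(r)) | (x >> np.uint64(64 - r))


def _fmix64_np(k: np.ndarray) -> np.ndarray:
    k = k ^ (k >> np.uint64(33))
    k = k * np.uint64(0xFF51AFD7ED558CCD)
    k = k ^ (k >> np.uint64(33))
    k = k * np.uint64(0xC4CEB9FE1A85EC53)
    k = k ^ (k >> np.uint64(33))
    return k


def murmur3_low64_batch(keys: np.ndarray, seed: int = 0) -> np.ndarray:
    """Vectorised h1 for a [N, L] uint8 array of equal-length keys, L <= 15.

    Bit-identical to ``murmur3_low64`` on each row.
    """
    keys = np.ascontiguousarray(keys, dtype=np.uint8)
    if keys.ndim != 2:
        raise ValueError("keys must be a 2-D [N, L] uint8 array")
    n, length = keys.shape
    if length > 15:
        raise ValueError("vectorised path supports key length <= 15 bytes")

    with np.errstate(over="ignore"):
        h1 = np.full(n, np.uint64(seed & _MASK64))
        h2 = h1.copy()

        k1 = np.zeros(n, dtype=np.uint64)
        k2 = np.zeros(n, dtype=np.uint64)
        for i in range(length - 1, 7, -1):
            k2 ^= keys[:, i].astype(np.uint64) << np.uint64((i - 8) * 8)
        for i in range(min(length, 8) - 1, -1, -1):
            k1 ^= keys[:, i].astype(np.uint64) << np.uint64(i * 8)

        if length >= 9:
            k2 = k2 * np.uint64(_C2)
            k2 = _rotl64_np(k2, 33)
            k2 = k2 * np.uint64(_C1)
            h2 = h2 ^ k2
        if length >= 1:
            k1 = k1 * np.uint64(_C1)
            k1 = _rotl64_np(k1, 31)
            k1 = k1 * np.uint64(_C2)
            h1 = h1 ^ k1

        h1 = h1 ^ np.uint64(length)
        h2 = h2 ^ np.uint64(length)
        h1 = h1 + h2
        h2 = h2 + h1
        h1 = _fmix64_np(h1)
        h2 = _fmix64_np(h2)
        h1 = h1 + h2
    return h1
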