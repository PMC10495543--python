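"""Read tokenization: canonical k-mers, vocabularies, hashing schemes, padding.

A sequencing read is turned into a sequence of integer token ids under one of
four schemes:

``char``
    one token per base (A, C, G, T, N).
``vocab``
    overlapping (stride-1 by default) k-mers mapped through an explicit
    canonical-k-mer vocabulary enumerated combinatorially.
``lsh``
    canonical k-mers bucketed by a Hamming locality-sensitive hash: a fixed
    seeded subset of m = ceil(0.8 k) positions is extracted and MurmurHash3
    of that subsequence taken modulo b buckets.  Two k-mers differing only at
    non-sampled positions collide by construction.
``hash``
    hash embeddings: each canonical k-mer selects q component vectors from a
    shared pool of b vectors via q independently seeded MurmurHash3 functions
    plus one importance-weight row; the embedding layer combines them as an
    importance-weighted sum.

Canonicalization (lexicographic minimum of a k-mer and its reverse
complement) makes every k-mer scheme strand-invariant.

All schemes share a special-id layout: PAD=0, UNK=1, CLS=2; scheme-specific
ids start at 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._murmur3 import murmur3_low64, murmur3_low64_batch

logger = logging.getLogger(__name__)

PAD_ID = 0
UNK_ID = 1
CLS_ID = 2
N_SPECIALS = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base code tables: A,C,G,T -> 0..3 (lexicographic), N and anything else -> 4
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """Canonical form: lexicographic minimum of ``s`` and its reverse complement."""
    if "N" in s:
        raise ValueError("canonical() is undefined for k-mers containing N")
    rc = revcomp(s)
    return s if s <= rc else rc


def kmer_tokens(read: str, k: int, stride: int = 1) -> List[str]:
    """Overlapping k-mer substrings of ``read`` at offsets 0, stride, 2*stride, ...

    Returns ``floor((L-k)/stride) + 1`` tokens for ``L >= k``, else ``[]``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    return [read[i : i + k] for i in range(0, len(read) - k + 1, stride)]


def _seq_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_ints(codes: np.ndarray, k: int, stride: int) -> Tuple[np.ndarray, np.ndarray]:
    """Base-4 integers of all k-windows plus a validity flag (no N in window)."""
    L = codes.shape[0]
    if L < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)[::stride]
    valid = (win < 4).all(axis=1)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    safe = np.where(win < 4, win, 0)
    return safe @ pow4, valid


def _revcomp_ints(ints: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of base-4 k-mer integers, vectorised."""
    out = np.zeros_like(ints)
    x = ints.copy()
    for _ in range(k):
        out = out * 4 + (3 - (x & 3))
        x >>= 2
    return out


def _canonical_ints(ints: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(ints, _revcomp_ints(ints, k))


def _ints_to_bytes(ints: np.ndarray, k: int) -> np.ndarray:
    """Base-4 k-mer integers -> [N, k] uint8 ASCII array."""
    n = ints.shape[0]
    out = np.empty((n, k), dtype=np.uint8)
    x = ints.copy()
    for j in range(k - 1, -1, -1):
        out[:, j] = _BASES[(x & 3).astype(np.intp)]
        x >>= 2
    return out


def canonical_kmer_count(k: int) -> int:
    """Number of canonical k-mers: 4^k/2 for odd k, (4^k + 4^{k/2})/2 for even."""
    if k % 2:
        return 4**k // 2
    return (4**k + 4 ** (k // 2)) // 2


@dataclass(frozen=True)
class Vocabulary:
    """Explicit canonical k-mer vocabulary.

    Ids start at ``N_SPECIALS`` and follow the lexicographic order of the
    canonical k-mers; a k-mer and its reverse complement share one id.
    """

    k: int
    size: int
    # maps any base-4 k-mer integer to its vocabulary id
    _id_table: np.ndarray = field(repr=False, compare=False)

    def id_of(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        if "N" in kmer:
            return UNK_ID
        ints, _ = _window_ints(_seq_codes(kmer), self.k, 1)
        return int(self._id_table[ints[0]])

    def kmers(self) -> List[str]:
        """All canonical k-mers in id order."""
        can = np.unique(_canonical_ints(np.arange(4**self.k, dtype=np.int64), self.k))
        return ["".join("ACGT"[c] for c in _int_codes(v, self.k)) for v in can]


def _int_codes(v: int, k: int) -> List[int]:
    return [(v >> (2 * (k - 1 - j))) & 3 for j in range(k)]


def build_vocab(k: int) -> Vocabulary:
    """Enumerate all canonical k-mers combinatorially and assign ids.

    Practical for ``k <= 13`` (the table has 4^k entries); the hashing schemes
    cover larger k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 13:
        raise ValueError("explicit vocabularies are limited to k <= 13")
    allk = np.arange(4**k, dtype=np.int64)
    can = _canonical_ints(allk, k)
    uniq, inv = np.unique(can, return_inverse=True)
    id_table = (inv + N_SPECIALS).astype(np.int64)
    return Vocabulary(k=k, size=N_SPECIALS + len(uniq), _id_table=id_table)


@dataclass(frozen=True)
class HashScheme:
    """Parameters of the hashed tokenization schemes.

    ``kind='lsh'``: b buckets, position subset of size ceil(0.8 k), one hash
    seed.  ``kind='hash'``: b shared pool rows, q component hashes with
    distinct seeds plus one importance hash over W importance rows.
    """

    kind: str  # 'lsh' | 'hash'
    k: int
    b: int
    q: int = 1
    importance_size: int = 0  # W; hash kind only
    seeds: Tuple[int, ...] = ()
    positions: Tuple[int, ...] = ()  # lsh kind only; sorted, len == m

    def __post_init__(self):
        if self.kind not in ("lsh", "hash"):
            raise ValueError(f"unknown hash scheme kind {self.kind!r}")
        if self.b < 2:
            raise ValueError("bucket count b must be >= 2")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("hash seeds must be distinct")


def make_lsh_scheme(k: int, b: int, seed: int = 0) -> HashScheme:
    """Hamming-LSH scheme: seeded random subset of m = ceil(0.8 k) positions."""
    m = int(np.ceil(0.8 * k))
    rng = np.random.default_rng(seed)
    positions = tuple(sorted(rng.choice(k, size=m, replace=False).tolist()))
    hash_seed = int(rng.integers(0, 2**31))
    return HashScheme(kind="lsh", k=k, b=b, q=1, seeds=(hash_seed,), positions=positions)


def make_hash_scheme(k: int, b: int, q: int = 6, importance_size: int = 2**16, seed: int = 0) -> HashScheme:
    """Hash-embedding scheme: q component hashes plus an importance hash.

    ``seeds[0]`` drives the importance-slot hash, ``seeds[1:]`` the q
    component hashes.
    """
    rng = np.random.default_rng(seed)
    seeds = tuple(int(s) for s in rng.choice(2**31, size=q + 1, replace=False))
    return HashScheme(kind="hash", k=k, b=b, q=q, importance_size=importance_size, seeds=seeds)


def lsh_bucket(kmer: str, scheme: HashScheme) -> int:
    """LSH bucket in [0, b) of a k-mer (canonicalised first)."""
    if scheme.kind != "lsh":
        raise ValueError("scheme is not an LSH scheme")
    if len(kmer) != scheme.k:
        raise ValueError(f"expected a {scheme.k}-mer, got length {len(kmer)}")
    can = canonical(kmer)
    sub = "".join(can[p] for p in scheme.positions)
    return murmur3_low64(sub.encode("ascii"), scheme.seeds[0]) % scheme.b


def hash_indices(kmer: str, scheme: HashScheme) -> Tuple[Tuple[int, ...], int]:
    """(q component ids in [0, b), importance-slot id in [0, W)) of a k-mer."""
    if scheme.kind != "hash":
        raise ValueError("scheme is not a hash-embedding scheme")
    if len(kmer) != scheme.k:
        raise ValueError(f"expected a {scheme.k}-mer, got length {len(kmer)}")
    can = canonical(kmer).encode("ascii")
    comps = tuple(murmur3_low64(can, s) % scheme.b for s in scheme.seeds[1:])
    imp = murmur3_low64(can, scheme.seeds[0]) % scheme.importance_size
    return comps, imp


@dataclass
class TokenStream:
    """Integer token ids for one read.

    ``ids`` has shape [n] for char/vocab/lsh schemes.  For the hash-embedding
    scheme ``component_ids`` [n, q] and ``importance_ids`` [n] are set as
    well, with ``ids`` holding the importance ids (used for padding logic).
    """

    ids: np.ndarray
    scheme: str
    read_id: str = ""
    component_ids: Optional[np.ndarray] = None
    importance_ids: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return int(self.ids.shape[0])


@dataclass
class PaddedBatch:
    """Batch of token streams padded to the longest stream.

    ``mask`` is True at real-token positions; padded positions hold PAD ids
    and are excluded from attention and mean reduction downstream.
    """

    ids: np.ndarray  # [B, n_max] int64
    mask: np.ndarray  # [B, n_max] bool
    component_ids: Optional[np.ndarray] = None  # [B, n_max, q] hash scheme
    importance_ids: Optional[np.ndarray] = None  # [B, n_max]

    @property
    def n_max(self) -> int:
        return int(self.ids.shape[1])


class Tokenizer:
    """Base interface: a scheme name, an embedding-table size, and encode()."""

    scheme: str
    k: int

    @property
    def table_size(self) -> int:  # rows of the (first) embedding table
        raise NotImplementedError

    def encode(self, seq: str) -> np.ndarray:
        raise NotImplementedError


class CharTokenizer(Tokenizer):
    """One token per base; A,C,G,T,N get ids 3..7."""

    scheme = "char"
    k = 1

    @property
    def table_size(self) -> int:
        return N_SPECIALS + 5

    def encode(self, seq: str) -> np.ndarray:
        codes = _seq_codes(seq)
        return (codes + N_SPECIALS).astype(np.int64)


class VocabTokenizer(Tokenizer):
    """Canonical k-mer vocabulary lookup; windows containing N map to UNK."""

    scheme = "vocab"

    def __init__(self, k: int, stride: int = 1, vocab: Optional[Vocabulary] = None):
        self.k = k
        self.stride = stride
        self.vocab = vocab if vocab is not None else build_vocab(k)
        if self.vocab.k != k:
            raise ValueError("vocabulary k does not match tokenizer k")

    @property
    def table_size(self) -> int:
        return self.vocab.size

    def encode(self, seq: str) -> np.ndarray:
        ints, valid = _window_ints(_seq_codes(seq), self.k, self.stride)
        ids = np.where(valid, self.vocab._id_table[ints], UNK_ID)
        return ids.astype(np.int64)


class LSHTokenizer(Tokenizer):
    """Hamming-LSH bucket ids, offset by the special-id count."""

    scheme = "lsh"

    def __init__(self, scheme_params: HashScheme, stride: int = 1):
        if scheme_params.kind != "lsh":
            raise ValueError("LSHTokenizer requires an 'lsh' HashScheme")
        self.params = scheme_params
        self.k = scheme_params.k
        self.stride = stride

    @property
    def table_size(self) -> int:
        return N_SPECIALS + self.params.b

    def encode(self, seq: str) -> np.ndarray:
        ints, valid = _window_ints(_seq_codes(seq), self.k, self.stride)
        ids = np.full(ints.shape[0], UNK_ID, dtype=np.int64)
        if valid.any():
            can = _canonical_ints(ints[valid], self.k)
            sub = _ints_to_bytes(can, self.k)[:, list(self.params.positions)]
            h = murmur3_low64_batch(sub, self.params.seeds[0])
            ids[valid] = (h % np.uint64(self.params.b)).astype(np.int64) + N_SPECIALS
        return ids


class HashEmbedTokenizer(Tokenizer):
    """Hash-embedding indices: q component ids plus an importance-slot id.

    Special tokens use their special id in every component slot and in the
    importance slot; real k-mer ids are offset by the special count.
    """

    scheme = "hash"

    def __init__(self, scheme_params: HashScheme, stride: int = 1):
        if scheme_params.kind != "hash":
            raise ValueError("HashEmbedTokenizer requires a 'hash' HashScheme")
        self.params = scheme_params
        self.k = scheme_params.k
        self.stride = stride

    @property
    def table_size(self) -> int:
        return N_SPECIALS + self.params.b

    @property
    def importance_table_size(self) -> int:
        return N_SPECIALS + self.params.importance_size

    def encode(self, seq: str) -> np.ndarray:
        comp, imp = self.encode_hash(seq)
        return imp

    def encode_hash(self, seq: str) -> Tuple[np.ndarray, np.ndarray]:
        ints, valid = _window_ints(_seq_codes(seq), self.k, self.stride)
        n = ints.shape[0]
        comp = np.full((n, self.params.q), UNK_ID, dtype=np.int64)
        imp = np.full(n, UNK_ID, dtype=np.int64)
        if valid.any():
            can = _canonical_ints(ints[valid], self.k)
            if self.k <= 15:
                kb = _ints_to_bytes(can, self.k)
                for j, s in enumerate(self.params.seeds[1:]):
                    comp[valid, j] = (
                        murmur3_low64_batch(kb, s) % np.uint64(self.params.b)
                    ).astype(np.int64) + N_SPECIALS
                imp[valid] = (
                    murmur3_low64_batch(kb, self.params.seeds[0])
                    % np.uint64(self.params.importance_size)
                ).astype(np.int64) + N_SPECIALS
            else:
                idx = np.flatnonzero(valid)
                for row, v in zip(idx, can):
                    key = "".join("ACGT"[c] for c in _int_codes(int(v), self.k)).encode()
                    for j, s in enumerate(self.params.seeds[1:]):
                        comp[row, j] = murmur3_low64(key, s) % self.params.b + N_SPECIALS
                    imp[row] = (
                        murmur3_low64(key, self.params.seeds[0]) % self.params.importance_size
                        + N_SPECIALS
                    )
        return comp, imp


def make_tokenizer(
    scheme: str,
    k: int = 12,
    stride: int = 1,
    b: int = 2**22,
    q: int = 6,
    importance_size: int = 2**16,
    seed: int = 0,
) -> Tokenizer:
    """Factory over the four schemes: 'char', 'vocab', 'lsh', 'hash'."""
    if scheme == "char":
        return CharTokenizer()
    if scheme == "vocab":
        return VocabTokenizer(k, stride=stride)
    if scheme == "lsh":
        return LSHTokenizer(make_lsh_scheme(k, b, seed=seed), stride=stride)
    if scheme == "hash":
        return HashEmbedTokenizer(
            make_hash_scheme(k, b, q=q, importance_size=importance_size, seed=seed),
            stride=stride,
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def encode_read(
    read: Union[str, "object"],
    tokenizer: Tokenizer,
    with_cls: bool = False,
    n_max: int = 256,
) -> TokenStream:
    """Encode one read into a TokenStream; truncates to ``n_max`` with a log line."""
    if hasattr(read, "sequence"):
        seq, rid = read.sequence, read.id
    else:
        seq, rid = str(read), ""
    ids = tokenizer.encode(seq)
    comp = imp = None
    if isinstance(tokenizer, HashEmbedTokenizer):
        comp, imp = tokenizer.encode_hash(seq)
        ids = imp
    if ids.shape[0] == 0:
        raise ValueError(
            f"read {rid or '<anonymous>'!r} of length {len(seq)} yields no tokens "
            f"(shorter than k={tokenizer.k})"
        )
    if with_cls:
        ids = np.concatenate(([CLS_ID], ids))
        if comp is not None:
            comp = np.concatenate((np.full((1, comp.shape[1]), CLS_ID, dtype=np.int64), comp))
            imp = np.concatenate(([CLS_ID], imp))
    if ids.shape[0] > n_max:
        logger.warning(
            "read %s: %d tokens truncated to n_max=%d", rid, ids.shape[0], n_max
        )
        ids = ids[:n_max]
        if comp is not None:
            comp, imp = comp[:n_max], imp[:n_max]
    return TokenStream(
        ids=ids, scheme=tokenizer.scheme, read_id=rid, component_ids=comp, importance_ids=imp
    )


def pad_batch(streams: Sequence[TokenStream]) -> PaddedBatch:
    """Pad a batch of streams to the longest one; mask marks real tokens."""
    if len(streams) == 0:
        raise ValueError("pad_batch requires at least one stream")
    n_max = max(len(s) for s in streams)
    B = len(streams)
    ids = np.full((B, n_max), PAD_ID, dtype=np.int64)
    mask = np.zeros((B, n_max), dtype=bool)
    has_hash = streams[0].component_ids is not None
    comp = imp = None
    if has_hash:
        q = streams[0].component_ids.shape[1]
        comp = np.full((B, n_max, q), PAD_ID, dtype=np.int64)
        imp = np.full((B, n_max), PAD_ID, dtype=np.int64)
    for i, s in enumerate(streams):
        n = len(s)
        ids[i, :n] = s.ids
        mask[i, :n] = True
        if has_hash:
            comp[i, :n] = s.component_ids
            imp[i, :n] = s.importance_ids
    return PaddedBatch(ids=ids, mask=mask, component_ids=comp, importance_ids=imp)
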