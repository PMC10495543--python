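"""Tokenization: canonical k-mers, vocabularies, hashing schemes, padding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from taxoformer.tokenization import (
    CLS_ID,
    PAD_ID,
    UNK_ID,
    HashEmbedTokenizer,
    LSHTokenizer,
    VocabTokenizer,
    build_vocab,
    canonical,
    canonical_kmer_count,
    encode_read,
    hash_indices,
    kmer_tokens,
    lsh_bucket,
    make_hash_scheme,
    make_lsh_scheme,
    make_tokenizer,
    pad_batch,
    revcomp,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)
SETTINGS = settings(max_examples=50, deadline=None, derandomize=True)


def brute_force_canonical_kmers(k):
    """Independent enumeration: all 4^k strings, canonicalised by hand."""
    from itertools import product

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = set()
    for tup in product("ACGT", repeat=k):
        s = "".join(tup)
        rc = "".join(comp[c] for c in reversed(s))
        out.add(min(s, rc))
    return sorted(out)


class TestRevcompCanonical:
    @pytest.mark.parametrize("s,expected", [("ACGT", "ACGT"), ("AAC", "GTT"), ("N", "N")])
    def test_revcomp_examples(self, s, expected):
        assert revcomp(s) == expected

    @SETTINGS
    @given(dna)
    def test_revcomp_involution(self, s):
        assert revcomp(revcomp(s)) == s

    @pytest.mark.parametrize("s,expected", [("TTG", "CAA"), ("ACG", "ACG")])
    def test_canonical_examples(self, s, expected):
        assert canonical(s) == expected

    @SETTINGS
    @given(dna)
    def test_canonical_strand_invariant(self, s):
        assert canonical(s) == canonical(revcomp(s))

    def test_revcomp_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestVocabulary:
    @pytest.mark.parametrize("k,n_canonical", [(1, 2), (2, 10), (3, 32)])
    def test_sizes_against_brute_force(self, k, n_canonical):
        assert len(brute_force_canonical_kmers(k)) == n_canonical
        assert build_vocab(k).size == 3 + n_canonical

    @pytest.mark.parametrize("k", range(1, 7))
    def test_closed_form_counts_exhaustive(self, k):
        expected = 4**k // 2 if k % 2 else (4**k + 4 ** (k // 2)) // 2
        assert len(brute_force_canonical_kmers(k)) == expected
        assert canonical_kmer_count(k) == expected
        assert build_vocab(k).size == 3 + expected

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_lexicographic_bijection_and_revcomp_identity(self, k):
        vocab = build_vocab(k)
        kmers = vocab.kmers()
        assert kmers == brute_force_canonical_kmers(k)
        ids = [vocab.id_of(s) for s in kmers]
        assert ids == list(range(3, vocab.size))
        for s in kmers:
            assert vocab.id_of(s) == vocab.id_of(revcomp(s))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            build_vocab(0)


class TestKmerTokens:
    def test_basic(self):
        assert kmer_tokens("ACGTA", 3) == ["ACG", "CGT", "GTA"]

    def test_read_shorter_than_k(self):
        assert kmer_tokens("AC", 5) == []

    @SETTINGS
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200), st.integers(1, 20), st.integers(1, 4))
    def test_token_count_law(self, read, k, stride):
        toks = kmer_tokens(read, k, stride)
        L = len(read)
        expected = (L - k) // stride + 1 if L >= k else 0
        assert len(toks) == expected
        assert all(len(t) == k for t in toks)

    def test_L150_k12_gives_139(self):
        assert len(kmer_tokens("A" * 150, 12)) == 139


class TestEncodeRead:
    def test_vocab_ids_above_specials(self):
        tok = make_tokenizer("vocab", k=3)
        ts = encode_read("ACGTA", tok)
        assert len(ts) == 3 and (ts.ids >= 3).all()

    def test_window_with_n_maps_to_unk(self):
        tok = make_tokenizer("vocab", k=3)
        ts = encode_read("ACNTA", tok)
        assert ts.ids.tolist() == [UNK_ID, UNK_ID, UNK_ID]

    def test_cls_prepended(self):
        tok = make_tokenizer("vocab", k=3)
        ts = encode_read("ACGTA", tok, with_cls=True)
        assert ts.ids[0] == CLS_ID and len(ts) == 4

    def test_too_short_read_errors_with_name(self):
        tok = make_tokenizer("vocab", k=6)
        from taxoformer.seqio import ReadRecord

        with pytest.raises(ValueError, match="shorty"):
            encode_read(ReadRecord(id="shorty", sequence="ACG"), tok)

    def test_truncation_to_n_max(self):
        tok = make_tokenizer("vocab", k=3)
        ts = encode_read("ACGT" * 50, tok, n_max=10)
        assert len(ts) == 10

    @SETTINGS
    @given(st.text(alphabet="ACGT", min_size=6, max_size=80))
    def test_token_multiset_strand_invariant(self, read):
        tok = make_tokenizer("vocab", k=4)
        fwd = encode_read(read, tok).ids
        rev = encode_read(revcomp(read), tok).ids
        assert sorted(fwd.tolist()) == sorted(rev.tolist())

    def test_char_scheme(self):
        tok = make_tokenizer("char")
        ts = encode_read("ACGTN", tok)
        assert ts.ids.tolist() == [3, 4, 5, 6, 7]


class TestLSH:
    scheme = make_lsh_scheme(k=15, b=2**22, seed=0)

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            kmer = "".join(rng.choice(list("ACGT"), 15))
            assert lsh_bucket(kmer, self.scheme) == lsh_bucket(revcomp(kmer), self.scheme)

    def test_range(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            kmer = "".join(rng.choice(list("ACGT"), 15))
            assert 0 <= lsh_bucket(kmer, self.scheme) < self.scheme.b

    def test_non_sampled_position_collides(self):
        # construct two k-mers differing only at a position the scheme ignores
        missing = sorted(set(range(15)) - set(self.scheme.positions))
        assert missing, "subsampling must drop ceil(0.8*15)=12 of 15 positions"
        p = missing[0]
        base = list("ACGTACGTACGTACG")
        other = base.copy()
        other[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[p]]
        a, b = "".join(base), "".join(other)
        # guard against the mutation flipping which strand is canonical
        if canonical(a)[self.scheme.positions[0]] == canonical(b)[self.scheme.positions[0]]:
            assert lsh_bucket(a, self.scheme) == lsh_bucket(b, self.scheme)

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError):
            lsh_bucket("ACGT", self.scheme)

    def test_tokenizer_matches_scalar_op(self):
        tok = LSHTokenizer(self.scheme)
        read = "ACGTTGCAATTGGCCAACGT"
        ids = encode_read(read, tok).ids
        expected = [lsh_bucket(k, self.scheme) + 3 for k in kmer_tokens(read, 15)]
        assert ids.tolist() == expected

    def test_bucket_occupancy_uniform(self):
        """Chi-square uniformity of bucket occupancy at b=2^10."""
        scheme = make_lsh_scheme(k=15, b=2**10, seed=3)
        tok = LSHTokenizer(scheme)
        rng = np.random.default_rng(5)
        # one long random sequence yields 2*10^5 random-ish k-mers
        seq = "".join(rng.choice(list("ACGT"), 200_000 + 14))
        ids = tok.encode(seq) - 3
        counts = np.bincount(ids, minlength=scheme.b)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=scheme.b - 1)
        assert p > 0.001


class TestHashEmbedding:
    scheme = make_hash_scheme(k=13, b=2**20, q=6, importance_size=2**16, seed=0)

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            kmer = "".join(rng.choice(list("ACGT"), 13))
            assert hash_indices(kmer, self.scheme) == hash_indices(revcomp(kmer), self.scheme)

    def test_components_mostly_distinct(self):
        rng = np.random.default_rng(1)
        n_all_equal = 0
        for _ in range(2000):
            kmer = "".join(rng.choice(list("ACGT"), 13))
            comps, _ = hash_indices(kmer, self.scheme)
            if len(set(comps)) == 1:
                n_all_equal += 1
        assert n_all_equal / 2000 < 0.01

    def test_deterministic(self):
        assert hash_indices("ACGTACGTACGTA", self.scheme) == hash_indices(
            "ACGTACGTACGTA", self.scheme
        )

    def test_tokenizer_matches_scalar_op(self):
        tok = HashEmbedTokenizer(self.scheme)
        read = "ACGTTGCAATTGGCCAACG"
        comp, imp = tok.encode_hash(read)
        for i, kmer in enumerate(kmer_tokens(read, 13)):
            comps, slot = hash_indices(kmer, self.scheme)
            assert comp[i].tolist() == [c + 3 for c in comps]
            assert imp[i] == slot + 3


class TestPadBatch:
    def test_equal_lengths_all_true_mask(self):
        tok = make_tokenizer("vocab", k=3)
        batch = pad_batch([encode_read("ACGTA", tok), encode_read("TTTTT", tok)])
        assert batch.mask.all() and batch.n_max == 3

    def test_mask_and_pad_layout(self):
        tok = make_tokenizer("vocab", k=3)
        batch = pad_batch([encode_read("ACGTA", tok), encode_read("ACGTACG", tok)])
        assert batch.mask[0].tolist() == [True, True, True, False, False]
        assert (batch.ids[0, 3:] == PAD_ID).all()
        # PAD never appears at a real-token position
        assert (batch.ids[batch.mask] != PAD_ID).all()

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError):
            pad_batch([])
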