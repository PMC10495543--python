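"""Encoder: positional encoding, attention vs brute force, masking, heads."""

import numpy as np
import pytest

from taxoformer._autodiff import Parameter, Tensor
from taxoformer.model import (
    BlockParams,
    EncoderConfig,
    HeadParams,
    MultiHeadParams,
    TransformerEncoderModel,
    attention,
    classify,
    encoder_block,
    input_encoding,
    multi_head,
    multilevel_forward,
    positional_encoding,
    reduce,
)
from taxoformer.tokenization import encode_read, make_tokenizer, pad_batch


def brute_force_attention(Q, K, V, mask=None):
    """Independent per-element double-loop implementation of scaled dot-product
    attention with exact zero weight on masked key positions."""
    n, d_k = Q.shape
    d_v = V.shape[1]
    out = np.zeros((n, d_v))
    for i in range(n):
        scores = []
        for j in range(n):
            if mask is not None and not mask[j]:
                scores.append(-np.inf)
            else:
                s = 0.0
                for a in range(d_k):
                    s += Q[i, a] * K[j, a]
                scores.append(s / np.sqrt(d_k))
        scores = np.array(scores)
        m = scores[np.isfinite(scores)].max()
        w = np.exp(scores - m)
        w[~np.isfinite(scores)] = 0.0
        w = w / w.sum()
        for j in range(n):
            out[i] += w[j] * V[j]
    return out


class TestPositionalEncoding:
    def test_first_frequency_is_one_and_value_at_p1(self):
        P = positional_encoding(4, 8).astype(np.float64)
        # f_0 = 1: component j=0 at position p=1 is sin(1)
        assert P[0, 0] == pytest.approx(np.sin(1.0), abs=1e-6)
        assert P[0, 1] == pytest.approx(np.cos(1.0), abs=1e-6)

    @pytest.mark.parametrize("d_model", [64, 128])
    def test_periods_and_bounds(self, d_model):
        n = 1000
        P = positional_encoding(n, d_model)
        assert (P >= -1).all() and (P <= 1).all()
        # j=0 has period exactly 2*pi: sin(p + 2*pi) == sin(p)
        p = np.arange(1, n + 1)
        assert np.allclose(P[:, 0], np.sin(p).astype(np.float32), atol=1e-6)
        # frequencies are a strictly decreasing geometric progression from 1,
        # so wavelengths increase monotonically from 2*pi to <= 2*pi*10000
        k = np.arange(d_model // 2)
        f = 10000.0 ** (-2 * k / d_model)
        wavelengths = 2 * np.pi / f
        assert wavelengths[0] == pytest.approx(2 * np.pi)
        assert (np.diff(wavelengths) > 0).all()
        assert wavelengths[-1] <= 2 * np.pi * 10000 + 1e-6

    def test_odd_d_model_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestInputEncoding:
    def test_zero_embeddings_give_positional_matrix(self):
        P = positional_encoding(5, 8)
        E = input_encoding(Tensor(np.zeros((5, 8))), P)
        assert np.allclose(E.data, P)

    def test_scale_is_sqrt_d_model(self):
        S = np.random.default_rng(0).normal(size=(4, 16)).astype(np.float32)
        P = positional_encoding(4, 16)
        E = input_encoding(Tensor(S), P)
        assert np.allclose(E.data - P, S * 4.0, atol=1e-5)


class TestAttention:
    def test_single_position_returns_value_row(self):
        Q = np.ones((1, 4), dtype=np.float32)
        K = np.ones((1, 4), dtype=np.float32)
        V = np.array([[1.0, 2.0, 3.0]], dtype=np.float32)
        out = attention(Q, K, V)
        assert np.allclose(out.data, V)

    def test_constant_values_dominate(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(5, 4)).astype(np.float32)
        K = rng.normal(size=(5, 4)).astype(np.float32)
        V = np.tile(np.array([[1.0, -2.0]], dtype=np.float32), (5, 1))
        out = attention(Q, K, V)
        assert np.allclose(out.data, V, atol=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            d_k = int(rng.integers(1, 17))
            d_v = int(rng.integers(1, 17))
            Q = rng.normal(size=(n, d_k)).astype(np.float32)
            K = rng.normal(size=(n, d_k)).astype(np.float32)
            V = rng.normal(size=(n, d_v)).astype(np.float32)
            mask = None
            if n > 1 and rng.random() < 0.5:
                mask = rng.random(n) < 0.7
                mask[int(rng.integers(0, n))] = True  # keep softmax defined
            expected = brute_force_attention(
                Q.astype(np.float64), K.astype(np.float64), V.astype(np.float64), mask
            )
            got = attention(Q, K, V, mask=mask).data
            assert np.abs(got - expected).max() < 1e-5

    def test_all_masked_row_rejected(self):
        Q = K = V = np.ones((2, 3), dtype=np.float32)
        with pytest.raises(ValueError):
            attention(Q, K, V, mask=np.array([False, False]))

    def test_masked_positions_get_zero_weight(self):
        rng = np.random.default_rng(1)
        n = 6
        Q = rng.normal(size=(n, 4)).astype(np.float32)
        K = rng.normal(size=(n, 4)).astype(np.float32)
        V = rng.normal(size=(n, 4)).astype(np.float32)
        mask = np.array([True, True, True, False, False, True])
        base = attention(Q, K, V, mask=mask).data
        # perturbing masked value rows must not change anything
        V2 = V.copy()
        V2[~mask] += 100.0
        assert np.allclose(attention(Q, K, V2, mask=mask).data, base)


def tiny_model(h=4, d_model=32, n_blocks=1, reduction="mean", class_counts=(5,), seed=0, **kw):
    tok = make_tokenizer("vocab", k=3)
    cfg = EncoderConfig(d_model=d_model, n_blocks=n_blocks, d_ff=64, h=h,
                        reduction=reduction, n_max=64, **kw)
    return TransformerEncoderModel(cfg, tok, list(class_counts), seed=seed), tok


class TestMultiHead:
    def test_parameter_count_invariant_over_heads(self):
        counts = []
        for h in (1, 2, 4, 8):
            m, _ = tiny_model(h=h, d_model=64)
            counts.append(m.n_parameters())
        assert len(set(counts)) == 1

    def test_permutation_equivariance_without_positions(self):
        """With no positional encoding, permuting input rows permutes the
        output rows of the full encoder stack identically."""
        rng = np.random.default_rng(0)
        m, _ = tiny_model(h=4, d_model=16, n_blocks=2)
        n = 7
        E = rng.normal(size=(1, n, 16)).astype(np.float32)
        perm = rng.permutation(n)

        def run(x):
            t = Tensor(x)
            for blk in m.blocks:
                t = encoder_block(t, blk)
            return t.data

        out = run(E)
        out_perm = run(E[:, perm, :])
        assert np.abs(out_perm - out[:, perm, :]).max() < 1e-5

    def test_single_head_collapses_to_attention(self):
        rng = np.random.default_rng(3)
        d = 8
        E = rng.normal(size=(4, d)).astype(np.float32)
        p = MultiHeadParams(
            Wq=Parameter(rng.normal(size=(d, d)).astype(np.float32)),
            Wk=Parameter(rng.normal(size=(d, d)).astype(np.float32)),
            Wv=Parameter(rng.normal(size=(d, d)).astype(np.float32)),
            Wo=Parameter(np.eye(d, dtype=np.float32)),
            h=1,
        )
        got = multi_head(Tensor(E), p).data
        expected = attention(E @ p.Wq.data, E @ p.Wk.data, E @ p.Wv.data).data
        assert np.allclose(got, expected, atol=1e-5)


class TestPaddingInvariance:
    def test_appending_padding_changes_nothing(self):
        m, tok = tiny_model(reduction="mean")
        reads = ["ACGTACGTAC", "TTGGCCAATT"]
        short = pad_batch([encode_read(r, tok) for r in reads])
        # same reads plus one longer read forces extra padded columns
        longer = pad_batch([encode_read(r, tok) for r in reads + ["ACGT" * 10]])
        out_short = m.forward(short)[0].data
        out_long = m.forward(longer)[0].data[:2]
        assert np.abs(out_short - out_long).max() < 1e-5


class TestReduce:
    def test_mean_of_identical_rows(self):
        O = Tensor(np.tile(np.arange(4, dtype=np.float32), (3, 5, 1)))
        out = reduce(O, "mean")
        assert np.allclose(out.data, np.tile(np.arange(4), (3, 1)))

    def test_cls_returns_position_zero(self):
        rng = np.random.default_rng(0)
        O = rng.normal(size=(2, 5, 4)).astype(np.float32)
        assert np.allclose(reduce(Tensor(O), "cls").data, O[:, 0, :])

    def test_masked_rows_do_not_affect_mean(self):
        rng = np.random.default_rng(1)
        O = rng.normal(size=(2, 5, 4)).astype(np.float32)
        mask = np.array([[True, True, True, False, False]] * 2)
        base = reduce(Tensor(O), "mean", mask=mask).data
        O2 = O.copy()
        O2[:, 3:, :] += 50.0
        assert np.allclose(reduce(Tensor(O2), "mean", mask=mask).data, base)

    def test_concat_requires_w_red(self):
        with pytest.raises(ValueError):
            reduce(Tensor(np.zeros((2, 3, 4))), "concat")

    def test_concat_rejects_wrong_length(self):
        W = Parameter(np.zeros((12, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="concat"):
            reduce(Tensor(np.zeros((2, 5, 4), dtype=np.float32)), "concat", W_red=W)


class TestHeads:
    def test_classify_constant_bias(self):
        W = Parameter(np.zeros((8, 3), dtype=np.float32))
        b = Parameter(np.array([1.0, 2.0, 3.0], dtype=np.float32))
        out = classify(Tensor(np.random.default_rng(0).normal(size=(4, 8)).astype(np.float32)), W, b)
        assert np.allclose(out.data, np.tile([1, 2, 3], (4, 1)))

    def test_zero_transforms_give_independent_heads(self):
        m, tok = tiny_model(class_counts=(3, 7))
        batch = pad_batch([encode_read("ACGTACGTACGT", tok)])
        for T in m.heads.transforms:
            if T is not None:
                T.data[:] = 0.0
        interconnected = [t.data.copy() for t in m.forward(batch)]
        # independent heads: evaluate each MLP alone on the same backbone output
        m2 = TransformerEncoderModel(m.config, tok, [3, 7], seed=m.seed, interconnect=False)
        for p2, p in zip(m2.parameters(), [p for p in m.parameters() if not p.name.endswith(".T")]):
            p2.data = p.data.copy()
        independent = [t.data for t in m2.forward(batch)]
        for a, b in zip(interconnected, independent):
            assert np.allclose(a, b)

    def test_coarse_scores_inform_fine_level(self):
        m, tok = tiny_model(class_counts=(3, 7))
        x = Tensor(np.random.default_rng(0).normal(size=(2, 32)).astype(np.float32))
        base = multilevel_forward(x, m.heads)
        # shift the genus-level MLP bias; the species scores must move unless T=0
        m.heads.mlps[0][3].data += 1.0  # b2 of level 0
        shifted = multilevel_forward(x, m.heads)
        assert not np.allclose(base[1].data, shifted[1].data)

    def test_single_level_is_plain_linear_classifier(self):
        m, tok = tiny_model(class_counts=(5,))
        batch = pad_batch([encode_read("ACGTACGTACGT", tok)])
        out = m.forward(batch)
        assert len(out) == 1 and out[0].data.shape == (1, 5)


class TestLayerNormProperty:
    def test_rows_standardised_before_gain_bias(self):
        from taxoformer._autodiff import layer_norm

        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(2.0, 3.0, size=(6, 32)).astype(np.float32))
        g = Parameter(np.ones(32, dtype=np.float32))
        b = Parameter(np.zeros(32, dtype=np.float32))
        y = layer_norm(x, g, b).data
        assert np.abs(y.mean(axis=-1)).max() < 1e-5
        assert np.abs(y.var(axis=-1) - 1).max() < 1e-3


class TestConfigValidation:
    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(d_model=64, h=5)

    @pytest.mark.parametrize("n_blocks", [1, 2, 3, 4])
    def test_block_range_accepted(self, n_blocks):
        m, tok = tiny_model(n_blocks=n_blocks, d_model=16)
        batch = pad_batch([encode_read("ACGTACGT", tok)])
        assert m.forward(batch)[0].data.shape == (1, 5)


class TestCheckpoint:
    def test_round_trip_bitwise(self, tmp_path):
        m, tok = tiny_model(class_counts=(3, 4))
        batch = pad_batch([encode_read("ACGTACGTACGT", tok)])
        before = [t.data.copy() for t in m.forward(batch)]
        m.save(tmp_path / "ckpt")
        m2 = TransformerEncoderModel.load(tmp_path / "ckpt")
        after = [t.data for t in m2.forward(batch)]
        for a, b in zip(before, after):
            assert (a == b).all()

    def test_forward_deterministic_in_eval_mode(self):
        m, tok = tiny_model(dropout=0.1)
        batch = pad_batch([encode_read("ACGTACGTACGT", tok)])
        a = m.forward(batch, training=False)[0].data
        b = m.forward(batch, training=False)[0].data
        assert (a == b).all()
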