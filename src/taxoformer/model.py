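"""The transformer encoder and its classification heads.

Architecture, in order: token embedding (explicit vocabulary, LSH-bucket
table, or hash-embedding pool), sinusoidal positional encoding added to the
scaled embeddings, a stack of post-norm encoder blocks (masked multi-head
self-attention -> add & layer-norm -> position-wise ReLU MLP -> add &
layer-norm), a sequence reduction (masked mean, cls token, or learned
concatenation), and either a single linear classifier or interconnected
multi-level heads in which each taxonomic level's scores receive a linear
transform of the previous (coarser) level's scores:

    y_i = MLP_i(x_b) + T_{i-1} y_{i-1},      T_0 = 0.

Attention uses scaled dot products (per-head scale 1/sqrt(d_k)) with an
additive -inf mask on padded key positions, so padding receives exactly zero
attention weight.  All trainable state lives in ``Parameter`` tensors from
the autodiff tape; the functional operations (``attention``, ``multi_head``,
``encoder_block``, ...) are usable standalone on plain arrays for analysis
and testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._autodiff import (
    DTYPE,
    Adam,
    Parameter,
    Tensor,
    concat,
    cross_entropy,
    dropout,
    embedding,
    layer_norm,
    softmax,
)
from .tokenization import (
    CLS_ID,
    HashEmbedTokenizer,
    PaddedBatch,
    Tokenizer,
    make_tokenizer,
)


@dataclass
class EncoderConfig:
    """Transformer hyperparameters.

    The evaluated grid in the original study: d_model 64/128, 1-4 encoder
    blocks, d_ff 256/512, mean/cls reduction, dropout 0.0/0.1.  The head
    count h is free (d_model must divide evenly); d_k = d_v = d_model / h so
    the trainable parameter count is invariant in h.
    """

    d_model: int = 64
    n_blocks: int = 1
    d_ff: int = 256
    h: int = 8
    reduction: str = "mean"  # 'mean' | 'cls' | 'concat'
    dropout: float = 0.0
    n_max: int = 256

    def __post_init__(self):
        if self.d_model <= 0 or self.n_blocks <= 0 or self.d_ff <= 0 or self.h <= 0:
            raise ValueError("all EncoderConfig sizes must be positive")
        if self.d_model % self.h:
            raise ValueError(f"d_model={self.d_model} not divisible by h={self.h}")
        if self.reduction not in ("mean", "cls", "concat"):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def d_k(self) -> int:
        return self.d_model // self.h


def positional_encoding(n: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding for positions p = 1..n.

    Component j = 2k holds sin(f_k p), j = 2k+1 holds cos(f_k p), with
    frequencies f_k = 10000^{-2k/d_model} forming a geometric progression
    from 1 down to 1/10000 — wavelengths grow monotonically from 2*pi to
    2*pi*10000.  Entries lie in [-1, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if d_model < 2 or d_model % 2:
        raise ValueError("d_model must be a positive even number")
    p = np.arange(1, n + 1, dtype=np.float64)[:, None]
    k = np.arange(d_model // 2, dtype=np.float64)[None, :]
    f = 10000.0 ** (-2.0 * k / d_model)
    P = np.empty((n, d_model), dtype=np.float64)
    P[:, 0::2] = np.sin(f * p)
    P[:, 1::2] = np.cos(f * p)
    return P.astype(DTYPE)


def input_encoding(S: Tensor, P: np.ndarray) -> Tensor:
    """Scale token embeddings by sqrt(d_model) and add the positional matrix."""
    d_model = S.shape[-1]
    if P.shape[-2:] != S.shape[-2:]:
        raise ValueError(f"positional matrix {P.shape} does not match embeddings {S.shape}")
    return S * float(np.sqrt(d_model)) + Tensor(P)


def _key_mask_bias(mask: Optional[np.ndarray], n: int) -> Optional[np.ndarray]:
    """Additive attention bias: 0 at real keys, -inf at masked keys."""
    if mask is None:
        return None
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("a sequence with every position masked has no valid softmax")
    if mask.all():  # nothing padded: the bias would be identically zero
        return None
    bias = np.where(mask, 0.0, -np.inf).astype(DTYPE)
    return bias.reshape(mask.shape[:-1] + (1, n))


def attention(
    Q: Union[Tensor, np.ndarray],
    K: Union[Tensor, np.ndarray],
    V: Union[Tensor, np.ndarray],
    mask: Optional[np.ndarray] = None,
) -> Tensor:
    """Scaled dot-product attention softmax(Q K^T / sqrt(d_k) + mask) V.

    ``mask`` flags real (attendable) key positions; masked columns receive
    exactly zero weight.  Works on arrays of shape [..., n, d].
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    d_k = Q.shape[-1]
    n = K.shape[-2]
    # fold the 1/sqrt(d_k) scale into Q (n*d_k entries instead of n*n)
    Qs = Q * float(1.0 / np.sqrt(d_k))
    scores = Qs @ K.transpose(*range(K.data.ndim - 2), K.data.ndim - 1, K.data.ndim - 2)
    bias = _key_mask_bias(mask, n)
    if bias is not None:
        scores = scores + Tensor(np.broadcast_to(bias, scores.shape).copy())
    w = softmax(scores, axis=-1, has_neg_inf=bias is not None)
    return w @ V


@dataclass
class MultiHeadParams:
    """Projections for all heads, stored fused: [d_model, h*d_k] etc."""

    Wq: Parameter
    Wk: Parameter
    Wv: Parameter
    Wo: Parameter  # [h*d_v, d_model]
    h: int


def multi_head(E: Tensor, params: MultiHeadParams, mask: Optional[np.ndarray] = None) -> Tensor:
    """Multi-head self-attention: per-head projections, attention, concat, W^O."""
    B = E.shape[0] if E.data.ndim == 3 else None
    n, d_model = E.shape[-2], E.shape[-1]
    h = params.h
    d_k = params.Wq.shape[1] // h

    def split_heads(x: Tensor) -> Tensor:
        # [B, n, h*d_k] -> [B, h, n, d_k]
        if B is None:
            return x.reshape(n, h, d_k).transpose(1, 0, 2)
        return x.reshape(B, n, h, d_k).transpose(0, 2, 1, 3)

    Q = split_heads(E @ params.Wq)
    K = split_heads(E @ params.Wk)
    V = split_heads(E @ params.Wv)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        key_mask = mask[:, None, None, :] if mask.ndim == 2 else mask[None, None, :]
        key_mask = np.broadcast_to(key_mask, Q.shape[:-2] + (1, n))[..., 0, :]
    else:
        key_mask = None
    A = attention(Q, K, V, mask=key_mask)
    if B is None:
        A = A.transpose(1, 0, 2).reshape(n, h * d_k)
    else:
        A = A.transpose(0, 2, 1, 3).reshape(B, n, h * d_k)
    return A @ params.Wo


@dataclass
class BlockParams:
    """One encoder block: attention + two layer norms + position-wise MLP."""

    mha: MultiHeadParams
    ln1_g: Parameter
    ln1_b: Parameter
    W1: Parameter
    b1: Parameter
    W2: Parameter
    b2: Parameter
    ln2_g: Parameter
    ln2_b: Parameter


def encoder_block(
    E: Tensor,
    params: BlockParams,
    mask: Optional[np.ndarray] = None,
    drop_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    training: bool = False,
) -> Tensor:
    """Post-norm block: N = LN(MHA(E) + E); O = LN(MLP(N) + N)."""
    Z = multi_head(E, params.mha, mask=mask)
    if training and drop_rate > 0:
        Z = dropout(Z, drop_rate, rng, training)
    N = layer_norm(Z + E, params.ln1_g, params.ln1_b)
    Hidden = (N @ params.W1 + params.b1).relu()
    M = Hidden @ params.W2 + params.b2
    if training and drop_rate > 0:
        M = dropout(M, drop_rate, rng, training)
    return layer_norm(M + N, params.ln2_g, params.ln2_b)


def reduce(
    O: Tensor,
    mode: str,
    mask: Optional[np.ndarray] = None,
    W_red: Optional[Parameter] = None,
) -> Tensor:
    """Collapse the token dimension: masked mean, cls position, or learned concat."""
    if mode == "mean":
        if mask is None:
            return O.mean(axis=-2)
        m = np.asarray(mask, dtype=DTYPE)
        counts = m.sum(axis=-1, keepdims=True)
        weighted = O * Tensor(m[..., None])
        return weighted.sum(axis=-2) * Tensor(1.0 / counts)
    if mode == "cls":
        return O[:, 0, :] if O.data.ndim == 3 else O[0]
    if mode == "concat":
        if W_red is None:
            raise ValueError("concat reduction requires W_red (fixed sequence length)")
        B = O.shape[0]
        flat = O.reshape(B, O.shape[1] * O.shape[2])
        if flat.shape[1] != W_red.shape[0]:
            raise ValueError(
                f"concat reduction built for n*d_model={W_red.shape[0]}, got {flat.shape[1]} "
                "(variable-length batches are incompatible with concat)"
            )
        return flat @ W_red
    raise ValueError(f"unknown reduction {mode!r}")


@dataclass
class HeadParams:
    """Classification heads, coarse -> fine, with interconnection transforms.

    Level i owns an MLP (single hidden layer, ReLU) from the backbone output
    to M_i class scores, and for i > 0 a transform T of the previous level's
    scores.  A single-level model degenerates to one linear classifier.
    """

    mlps: List[Tuple[Parameter, ...]]  # per level: (W1, b1, W2, b2) or (W, b)
    transforms: List[Optional[Parameter]]  # per level; [M_{i-1}, M_i]; None at level 0
    class_counts: List[int]


def classify(O_red: Tensor, W: Parameter, b: Parameter) -> Tensor:
    """Single-level linear classifier: unnormalised scores O_red W + b."""
    return O_red @ W + b


def multilevel_forward(x_b: Tensor, heads: HeadParams) -> List[Tensor]:
    """Evaluate interconnected heads coarse -> fine; level 0 has no carry-in."""
    outputs: List[Tensor] = []
    prev: Optional[Tensor] = None
    for i, mlp in enumerate(heads.mlps):
        if len(mlp) == 2:
            W, b = mlp
            y = x_b @ W + b
        else:
            W1, b1, W2, b2 = mlp
            y = ((x_b @ W1 + b1).relu()) @ W2 + b2
        T = heads.transforms[i]
        if T is not None:
            if prev is None:
                raise ValueError("interconnection transform present at the first level")
            y = y + prev @ T
        outputs.append(y)
        prev = outputs[-1]
    return outputs


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class TransformerEncoderModel:
    """The full read classifier: embedding, encoder stack, reduction, heads.

    ``class_counts`` is a list of class counts per taxonomic level (coarse to
    fine); a single-element list builds the single-level linear classifier.
    """

    def __init__(
        self,
        config: EncoderConfig,
        tokenizer: Tokenizer,
        class_counts: Sequence[int],
        seed: int = 0,
        head_hidden: Optional[int] = None,
        interconnect: bool = True,
    ):
        self.config = config
        self.tokenizer = tokenizer
        self.class_counts = [int(c) for c in class_counts]
        self.seed = int(seed)
        self.interconnect = bool(interconnect)
        self.head_hidden = head_hidden
        rng = np.random.default_rng(seed)
        d = config.d_model

        emb_scale = d ** -0.5
        self.embed = Parameter(
            rng.normal(0.0, emb_scale, size=(tokenizer.table_size, d)).astype(DTYPE),
            name="embedding",
        )
        self.importance: Optional[Parameter] = None
        if isinstance(tokenizer, HashEmbedTokenizer):
            q = tokenizer.params.q
            self.importance = Parameter(
                np.full((tokenizer.importance_table_size, q), 1.0 / q, dtype=DTYPE),
                name="importance",
            )

        self.blocks: List[BlockParams] = []
        for i in range(config.n_blocks):
            mha = MultiHeadParams(
                Wq=Parameter(_he_uniform(rng, d, (d, d)), name=f"b{i}.Wq"),
                Wk=Parameter(_he_uniform(rng, d, (d, d)), name=f"b{i}.Wk"),
                Wv=Parameter(_he_uniform(rng, d, (d, d)), name=f"b{i}.Wv"),
                Wo=Parameter(_he_uniform(rng, d, (d, d)), name=f"b{i}.Wo"),
                h=config.h,
            )
            self.blocks.append(
                BlockParams(
                    mha=mha,
                    ln1_g=Parameter(np.ones(d, dtype=DTYPE), name=f"b{i}.ln1_g"),
                    ln1_b=Parameter(np.zeros(d, dtype=DTYPE), name=f"b{i}.ln1_b"),
                    W1=Parameter(_he_uniform(rng, d, (d, config.d_ff)), name=f"b{i}.W1"),
                    b1=Parameter(np.zeros(config.d_ff, dtype=DTYPE), name=f"b{i}.b1"),
                    W2=Parameter(_he_uniform(rng, config.d_ff, (config.d_ff, d)), name=f"b{i}.W2"),
                    b2=Parameter(np.zeros(d, dtype=DTYPE), name=f"b{i}.b2"),
                    ln2_g=Parameter(np.ones(d, dtype=DTYPE), name=f"b{i}.ln2_g"),
                    ln2_b=Parameter(np.zeros(d, dtype=DTYPE), name=f"b{i}.ln2_b"),
                )
            )

        self.W_red: Optional[Parameter] = None
        if config.reduction == "concat":
            self.W_red = Parameter(
                _he_uniform(rng, config.n_max * d, (config.n_max * d, d)), name="W_red"
            )

        mlps: List[Tuple[Parameter, ...]] = []
        transforms: List[Optional[Parameter]] = []
        hidden = head_hidden if head_hidden is not None else d
        single = len(self.class_counts) == 1
        for i, m in enumerate(self.class_counts):
            # output layers start small so initial logits are near zero and the
            # initial loss sits at ln(m) (near-uniform class probabilities)
            if single:
                mlps.append(
                    (
                        Parameter(0.3 * _he_uniform(rng, d, (d, m)), name="head.W"),
                        Parameter(np.zeros(m, dtype=DTYPE), name="head.b"),
                    )
                )
            else:
                mlps.append(
                    (
                        Parameter(_he_uniform(rng, d, (d, hidden)), name=f"h{i}.W1"),
                        Parameter(np.zeros(hidden, dtype=DTYPE), name=f"h{i}.b1"),
                        Parameter(0.3 * _he_uniform(rng, hidden, (hidden, m)), name=f"h{i}.W2"),
                        Parameter(np.zeros(m, dtype=DTYPE), name=f"h{i}.b2"),
                    )
                )
            if i == 0 or not self.interconnect:
                transforms.append(None)
            else:
                prev_m = self.class_counts[i - 1]
                transforms.append(
                    Parameter(0.3 * _he_uniform(rng, prev_m, (prev_m, m)), name=f"h{i}.T")
                )
        self.heads = HeadParams(mlps=mlps, transforms=transforms, class_counts=self.class_counts)

        # positional matrix cache
        self._P = positional_encoding(config.n_max, d)
        self._drop_rng = np.random.default_rng(rng.integers(0, 2**31))

    # ------------------------------------------------------------------
    def parameters(self) -> List[Parameter]:
        out = [self.embed]
        if self.importance is not None:
            out.append(self.importance)
        for b in self.blocks:
            out += [b.mha.Wq, b.mha.Wk, b.mha.Wv, b.mha.Wo, b.ln1_g, b.ln1_b,
                    b.W1, b.b1, b.W2, b.b2, b.ln2_g, b.ln2_b]
        if self.W_red is not None:
            out.append(self.W_red)
        for mlp in self.heads.mlps:
            out += list(mlp)
        for T in self.heads.transforms:
            if T is not None:
                out.append(T)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def embed_tokens(self, batch: PaddedBatch) -> Tensor:
        """Token embeddings [B, n, d_model] for any scheme."""
        if self.importance is not None and batch.component_ids is not None:
            pool = embedding(self.embed, batch.component_ids)  # [B, n, q, d]
            imp = embedding(self.importance, batch.importance_ids)  # [B, n, q]... rows are q-vectors
            # importance table has one q-vector per slot; weight and sum components
            w = imp.reshape(*imp.shape, 1)  # [B, n, q, 1]
            return (pool * w).sum(axis=-2)
        return embedding(self.embed, batch.ids)

    def forward(self, batch: PaddedBatch, training: bool = False) -> List[Tensor]:
        """Unnormalised class scores per level for a padded batch."""
        cfg = self.config
        n = batch.n_max
        if n > cfg.n_max:
            raise ValueError(f"batch length {n} exceeds configured n_max {cfg.n_max}")
        S = self.embed_tokens(batch)
        E = input_encoding(S, self._P[:n])
        if training and cfg.dropout > 0:
            E = dropout(E, cfg.dropout, self._drop_rng, training)
        mask = batch.mask
        for blk in self.blocks:
            E = encoder_block(
                E, blk, mask=mask, drop_rate=cfg.dropout, rng=self._drop_rng, training=training
            )
        O_red = reduce(E, cfg.reduction, mask=mask, W_red=self.W_red)
        if len(self.class_counts) == 1:
            W, b = self.heads.mlps[0]
            return [classify(O_red, W, b)]
        return multilevel_forward(O_red, self.heads)

    # ------------------------------------------------------------------
    def _meta(self) -> dict:
        tok = self.tokenizer
        meta = {
            "config": asdict(self.config),
            "class_counts": self.class_counts,
            "seed": self.seed,
            "interconnect": self.interconnect,
            "head_hidden": self.head_hidden,
            "scheme": tok.scheme,
            "k": tok.k,
            "stride": getattr(tok, "stride", 1),
        }
        if tok.scheme in ("lsh", "hash"):
            p = tok.params
            meta["hash_scheme"] = {
                "kind": p.kind, "k": p.k, "b": p.b, "q": p.q,
                "importance_size": p.importance_size,
                "seeds": list(p.seeds), "positions": list(p.positions),
            }
        return meta

    def save(self, directory: Union[str, Path], extra_meta: Optional[dict] = None) -> None:
        """Write config (JSON) and weights (NPZ) to a checkpoint directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = self._meta()
        if extra_meta:
            meta.update(extra_meta)
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "TransformerEncoderModel":
        """Rebuild a model bit-for-bit from a checkpoint directory."""
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        tokenizer = tokenizer_from_meta(meta)
        model = cls(
            EncoderConfig(**meta["config"]),
            tokenizer,
            meta["class_counts"],
            seed=meta["seed"],
            head_hidden=meta["head_hidden"],
            interconnect=meta["interconnect"],
        )
        with np.load(directory / "weights.npz") as z:
            for i, p in enumerate(model.parameters()):
                p.data = z[f"p{i}"].astype(DTYPE)
        return model


def tokenizer_from_meta(meta: dict) -> Tokenizer:
    """Reconstruct the tokenizer recorded in checkpoint metadata."""
    from .tokenization import (
        CharTokenizer,
        HashEmbedTokenizer,
        HashScheme,
        LSHTokenizer,
        VocabTokenizer,
    )

    scheme = meta["scheme"]
    stride = meta.get("stride", 1)
    if scheme == "char":
        return CharTokenizer()
    if scheme == "vocab":
        return VocabTokenizer(meta["k"], stride=stride)
    hs = meta["hash_scheme"]
    params = HashScheme(
        kind=hs["kind"], k=hs["k"], b=hs["b"], q=hs["q"],
        importance_size=hs["importance_size"],
        seeds=tuple(hs["seeds"]), positions=tuple(hs["positions"]),
    )
    if scheme == "lsh":
        return LSHTokenizer(params, stride=stride)
    return HashEmbedTokenizer(params, stride=stride)
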