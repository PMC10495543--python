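"""Scikit-learn style estimator wrapping the transformer read classifier.

``TransformerReadClassifier`` follows the sklearn contract: hyperparameters
in ``__init__``, ``fit(X, y)`` with fitted attributes trailing an
underscore, ``predict``/``predict_proba``, and ``get_params``/``set_params``
via ``BaseEstimator`` — so it composes with sklearn model selection.  ``X``
is a sequence of DNA strings (or ReadRecords); ``y`` is a 1-D array of class
labels, or a 2-D array [n, L] of labels at L taxonomic levels ordered coarse
to fine (e.g. genus, species), which builds the interconnected multi-level
heads.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .inference import Prediction, classify_reads
from .model import EncoderConfig, TransformerEncoderModel, tokenizer_from_meta
from .seqio import ReadRecord
from .tokenization import TokenStream, encode_read, make_tokenizer, pad_batch
from .training import TrainConfig, TrainState, class_weights, train


def _as_sequence(x) -> str:
    return x.sequence if isinstance(x, ReadRecord) else str(x)


class TransformerReadClassifier(BaseEstimator, ClassifierMixin):
    """Transformer-encoder classifier for short DNA reads.

    Parameters follow the evaluated hyperparameter grid (d_model, encoder
    blocks, d_ff, reduction, dropout) plus the tokenization scheme
    ('char', 'vocab', 'lsh', 'hash').  Desk-scale training defaults (batch
    64, lr 1e-3, a few thousand steps) replace the reference-scale protocol
    (batch 2048, lr 0.01, hundreds of thousands of steps); pass overrides
    for larger runs.
    """

    def __init__(
        self,
        scheme: str = "vocab",
        k: int = 6,
        stride: int = 1,
        b: int = 2**20,
        q: int = 6,
        importance_size: int = 2**16,
        d_model: int = 32,
        n_blocks: int = 1,
        d_ff: int = 256,
        h: int = 4,
        reduction: str = "mean",
        dropout: float = 0.0,
        n_max: int = 256,
        head_hidden: Optional[int] = None,
        interconnect: bool = True,
        lr: float = 2e-3,
        batch_size: int = 64,
        max_steps: int = 3000,
        patience: int = 500,
        val_interval: int = 100,
        val_fraction: float = 0.1,
        sparse_embedding: bool = False,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.scheme = scheme
        self.k = k
        self.stride = stride
        self.b = b
        self.q = q
        self.importance_size = importance_size
        self.d_model = d_model
        self.n_blocks = n_blocks
        self.d_ff = d_ff
        self.h = h
        self.reduction = reduction
        self.dropout = dropout
        self.n_max = n_max
        self.head_hidden = head_hidden
        self.interconnect = interconnect
        self.lr = lr
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.patience = patience
        self.val_interval = val_interval
        self.val_fraction = val_fraction
        self.sparse_embedding = sparse_embedding
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim == 1:
            y = y[:, None]
        self.n_levels_ = y.shape[1]
        self.classes_per_level_ = []
        codes = np.empty(y.shape, dtype=np.int64)
        for i in range(self.n_levels_):
            classes, inv = np.unique(y[:, i].astype(str), return_inverse=True)
            self.classes_per_level_.append(classes)
            codes[:, i] = inv
        # sklearn-style: classes_ is the finest level for 1-D targets
        self.classes_ = self.classes_per_level_[-1] if self.n_levels_ == 1 else self.classes_per_level_
        return codes

    def _tokenize(self, X) -> List[TokenStream]:
        with_cls = self.reduction == "cls"
        return [
            encode_read(_as_sequence(x), self._tokenizer, with_cls=with_cls, n_max=self.n_max)
            for x in X
        ]

    def fit(self, X, y) -> "TransformerReadClassifier":
        """Train on reads ``X`` with labels ``y`` (1-D, or [n, L] coarse->fine)."""
        X = list(X)
        if len(X) == 0:
            raise ValueError("empty training set")
        codes = self._encode_labels(y)
        if len(X) != codes.shape[0]:
            raise ValueError("X and y length mismatch")
        self._tokenizer = make_tokenizer(
            self.scheme, k=self.k, stride=self.stride, b=self.b, q=self.q,
            importance_size=self.importance_size, seed=self.random_state,
        )
        streams = self._tokenize(X)
        rng = np.random.default_rng(self.random_state)
        n = len(streams)
        order = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n > 1 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        if train_idx.size == 0:
            train_idx = order

        class_counts = [len(c) for c in self.classes_per_level_]
        config = EncoderConfig(
            d_model=self.d_model, n_blocks=self.n_blocks, d_ff=self.d_ff, h=self.h,
            reduction=self.reduction, dropout=self.dropout, n_max=self.n_max,
        )
        self.model_ = TransformerEncoderModel(
            config, self._tokenizer, class_counts,
            seed=self.random_state, head_hidden=self.head_hidden,
            interconnect=self.interconnect,
        )

        weights = None
        if self.n_levels_ > 1:
            weights = []
            for i in range(self.n_levels_):
                counts = np.bincount(codes[train_idx, i], minlength=class_counts[i])
                weights.append(class_weights(np.maximum(counts, 1)))

        bs = self.batch_size
        epoch_rng = np.random.default_rng(rng.integers(0, 2**31))

        def train_batches():
            perm = train_idx[epoch_rng.permutation(train_idx.size)]
            for s in range(0, perm.size, bs):
                idx = perm[s : s + bs]
                yield pad_batch([streams[j] for j in idx]), codes[idx]

        val_list = []
        for s in range(0, val_idx.size, bs):
            idx = val_idx[s : s + bs]
            val_list.append((pad_batch([streams[j] for j in idx]), codes[idx]))
        if not val_list:  # degenerate tiny input: validate on training data
            val_list = list(train_batches())

        tcfg = TrainConfig(
            lr=self.lr, batch_size=bs, max_steps=self.max_steps,
            patience=self.patience, val_interval=self.val_interval,
            seed=self.random_state, sparse_embedding=self.sparse_embedding,
        )
        self.train_state_ = train(self.model_, train_batches, val_list, tcfg, weights)
        self.history_ = self.train_state_.history
        self.level_names_ = (
            ["class"] if self.n_levels_ == 1 else [f"level{i}" for i in range(self.n_levels_)]
        )
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this TransformerReadClassifier is not fitted yet")

    def decision_function(self, X) -> Union[np.ndarray, List[np.ndarray]]:
        """Unnormalised class scores; a list of arrays for multi-level models."""
        self._check_fitted()
        streams = self._tokenize(list(X))
        outs = [[] for _ in range(self.n_levels_)]
        for s in range(0, len(streams), 256):
            batch = pad_batch(streams[s : s + 256])
            for i, t in enumerate(self.model_.forward(batch, training=False)):
                outs[i].append(t.data)
        scores = [np.concatenate(o, axis=0) for o in outs]
        return scores[0] if self.n_levels_ == 1 else scores

    def predict_proba(self, X) -> Union[np.ndarray, List[np.ndarray]]:
        """Softmax class probabilities (per level for multi-level models)."""
        scores = self.decision_function(X)
        levels = [scores] if self.n_levels_ == 1 else scores
        probs = []
        for z in levels:
            m = z.max(axis=-1, keepdims=True)
            e = np.exp(z - m)
            probs.append(e / e.sum(axis=-1, keepdims=True))
        return probs[0] if self.n_levels_ == 1 else probs

    def predict(self, X) -> np.ndarray:
        """Argmax class labels; shape [n] or [n, L] for multi-level models."""
        probs = self.predict_proba(X)
        if self.n_levels_ == 1:
            return self.classes_[probs.argmax(axis=-1)]
        cols = [
            self.classes_per_level_[i][p.argmax(axis=-1)] for i, p in enumerate(probs)
        ]
        return np.stack(cols, axis=1)

    def classify(self, reads, threshold: Optional[float] = None, paired: bool = False):
        """Thresholded classification of ReadRecords; yields Predictions."""
        self._check_fitted()
        thr = self.threshold if threshold is None else threshold
        return classify_reads(
            self.model_, reads, threshold=thr,
            level_names=self.level_names_,
            level_classes=[list(c) for c in self.classes_per_level_],
            paired=paired,
        )

    # ------------------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        """Checkpoint: encoder config + weights + label vocabularies."""
        self._check_fitted()
        extra = {
            "level_names": self.level_names_,
            "level_classes": [list(map(str, c)) for c in self.classes_per_level_],
            "estimator_params": self.get_params(),
        }
        self.model_.save(directory, extra_meta=extra)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "TransformerReadClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        est = cls(**meta["estimator_params"])
        est.model_ = TransformerEncoderModel.load(directory)
        est._tokenizer = est.model_.tokenizer
        est.classes_per_level_ = [np.asarray(c) for c in meta["level_classes"]]
        est.n_levels_ = len(est.classes_per_level_)
        est.classes_ = (
            est.classes_per_level_[-1] if est.n_levels_ == 1 else est.classes_per_level_
        )
        est.level_names_ = meta["level_names"]
        est.history_ = []
        return est
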