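"""Training: weighted cross-entropy, class weights, early stopping.

The optimizer is Adam (reference configuration: learning rate 0.01 at batch
size 2048; desk-scale runs use smaller batches and proportionally smaller
learning rates).  Validation loss is tracked every ``val_interval`` steps;
training stops when it has not improved for ``patience`` steps or at
``max_steps``, and the best-validation checkpoint (not the last) is
returned.

Single-level models train with plain cross-entropy (the read generator
balances the dataset at that level); multi-level models always apply
per-level class weights — the normalized inverse class counts — because a
set balanced at one taxonomic level is generally imbalanced at the others.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._autodiff import Adam, Tensor, cross_entropy
from .model import TransformerEncoderModel
from .tokenization import PaddedBatch

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings.

    Reference-scale defaults (lr 0.01, batch 2048, patience 50,000 steps)
    match the published training protocol; desk-scale experiments override
    them (batch 64, patience a few hundred steps).
    """

    lr: float = 0.01
    batch_size: int = 2048
    max_steps: int = 300_000
    patience: int = 50_000
    val_interval: int = 1000
    seed: int = 0
    sparse_embedding: bool = False
    mixed_precision: bool = False

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.max_steps, self.patience, self.val_interval) <= 0:
            raise ValueError("all TrainConfig values must be positive")
        if self.patience >= self.max_steps:
            raise ValueError("patience must be smaller than max_steps")


@dataclass
class TrainState:
    """Progress record: best validation loss and the logged history."""

    step: int = 0
    best_val_loss: float = float("inf")
    best_step: int = 0
    steps_since_improvement: int = 0
    stopped_early: bool = False
    # rows: (step, train_loss, val_loss, val_precision, val_recall)
    history: List[Tuple[int, float, float, float, float]] = field(default_factory=list)


def class_weights(counts: Sequence[int]) -> np.ndarray:
    """Normalized inverse class counts: w_j = (1/n_j) * C / sum_l (1/n_l).

    Mean-1 normalization keeps the weighted loss on the same scale as the
    unweighted loss (so the learning rate transfers); equal counts give all
    weights exactly 1, and scaling every count leaves the weights unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty class count vector")
    if (counts < 1).any():
        raise ValueError("every class present in training must have count >= 1")
    inv = 1.0 / counts
    return inv * counts.size / inv.sum()


def ce_loss(scores: np.ndarray, label: int) -> float:
    """Cross-entropy -log softmax(scores)[label], stabilised via log-sum-exp."""
    scores = np.asarray(scores, dtype=float)
    m = scores.max()
    lse = m + np.log(np.exp(scores - m).sum())
    return float(lse - scores[label])


def multilevel_loss(
    scores: Sequence[Tensor],
    labels: np.ndarray,
    weights: Optional[Sequence[Optional[np.ndarray]]] = None,
) -> Tensor:
    """Sum over levels of per-level weighted cross-entropy (batch mean).

    ``labels`` has shape [B, N_levels]; ``weights[i]`` is the per-class
    weight vector of level i (None for unweighted).  With all weights 1 this
    is exactly the sum of the per-level cross-entropies.
    """
    labels = np.atleast_2d(np.asarray(labels))
    if labels.shape[1] != len(scores):
        raise ValueError(
            f"label levels {labels.shape[1]} != score levels {len(scores)}"
        )
    total: Optional[Tensor] = None
    for i, y_hat in enumerate(scores):
        y = labels[:, i]
        sw = None
        if weights is not None and weights[i] is not None:
            sw = np.asarray(weights[i])[y]
        term = cross_entropy(y_hat, y, sample_weights=sw, reduction="mean")
        total = term if total is None else total + term
    return total


BatchStream = Union[Iterable, Callable[[], Iterable]]


def _epochs(stream: BatchStream):
    """Yield batches forever, restarting the stream when it is exhausted."""
    while True:
        it = stream() if callable(stream) else iter(stream)
        empty = True
        for item in it:
            empty = False
            yield item
        if empty:
            raise ValueError("empty training stream")


def _evaluate(
    model: TransformerEncoderModel,
    val_batches: List[Tuple[PaddedBatch, np.ndarray]],
    weights: Optional[Sequence[Optional[np.ndarray]]],
) -> Tuple[float, float, float]:
    """Validation loss plus read-level precision/recall at the finest level."""
    losses, n_total, n_correct = [], 0, 0
    for batch, labels in val_batches:
        scores = model.forward(batch, training=False)
        loss = multilevel_loss(scores, labels, weights)
        losses.append(float(loss.data) * labels.shape[0])
        n_total += labels.shape[0]
        fine = np.atleast_2d(labels)[:, -1]
        pred = scores[-1].data.argmax(axis=-1)
        n_correct += int((pred == fine).sum())
    loss = float(np.sum(losses) / n_total)
    # every read receives an argmax prediction here, so precision == recall
    acc = n_correct / n_total if n_total else 0.0
    return loss, acc, acc


def train(
    model: TransformerEncoderModel,
    train_stream: BatchStream,
    val_stream: BatchStream,
    config: TrainConfig,
    level_weights: Optional[Sequence[Optional[np.ndarray]]] = None,
) -> TrainState:
    """Optimize ``model`` in place; restores the best-validation weights.

    Streams yield ``(PaddedBatch, labels)`` pairs; ``labels`` is [B] for a
    single-level model or [B, N] coarse-to-fine.  Raises on a non-finite
    loss with the offending step in the message.
    """
    n_levels = len(model.class_counts)
    if level_weights is None and n_levels > 1:
        raise ValueError("multi-level training requires per-level class weights")
    opt = Adam(model.parameters(), lr=config.lr, sparse=config.sparse_embedding)
    state = TrainState()
    val_batches = list(val_stream() if callable(val_stream) else val_stream)
    if not val_batches:
        raise ValueError("empty validation stream")
    best_params: Optional[List[np.ndarray]] = None

    for batch, labels in _epochs(train_stream):
        if state.step >= config.max_steps:
            break
        state.step += 1
        scores = model.forward(batch, training=True)
        loss = multilevel_loss(scores, labels, level_weights)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss {loss_val} at step {state.step}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()

        if state.step % config.val_interval == 0 or state.step == config.max_steps:
            val_loss, val_p, val_r = _evaluate(model, val_batches, level_weights)
            state.history.append((state.step, loss_val, val_loss, val_p, val_r))
            logger.info(
                "step %d train_loss %.4f val_loss %.4f val_precision %.4f val_recall %.4f",
                state.step, loss_val, val_loss, val_p, val_r,
            )
            if val_loss < state.best_val_loss:
                state.best_val_loss = val_loss
                state.best_step = state.step
                state.steps_since_improvement = 0
                best_params = [p.data.copy() for p in model.parameters()]
            else:
                state.steps_since_improvement = state.step - state.best_step
                if state.steps_since_improvement > config.patience:
                    state.stopped_early = True
                    break

    if best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return state
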