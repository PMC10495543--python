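"""Inference: read classification, paired-end averaging, abundance profiles.

Paired-end reads are scored separately per mate; the unnormalised scores are
component-wise averaged *before* the softmax (averaging probabilities
instead can change the ranking, so the order matters).  A read is assigned
its argmax class when the softmax confidence reaches the threshold
(default 0.5) and reported as unclassified otherwise; multi-level models
threshold each level independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .metrics import UNCLASSIFIED
from .model import TransformerEncoderModel
from .seqio import ReadRecord
from .tokenization import encode_read, pad_batch


@dataclass
class Prediction:
    """Per-read call: class id (or 'unclassified') and confidence per level."""

    read_id: str
    labels: Dict[str, str]  # level name -> class id or 'unclassified'
    confidences: Dict[str, float]


@dataclass
class AbundanceProfile:
    """Read fractions per class among classified reads at one level."""

    fractions: Dict[str, float]
    n_classified: int
    n_total: int


def _softmax(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=-1, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=-1, keepdims=True)


def _batch_scores(
    model: TransformerEncoderModel, reads: Sequence[ReadRecord], with_cls: bool
) -> List[np.ndarray]:
    streams = [
        encode_read(r, model.tokenizer, with_cls=with_cls, n_max=model.config.n_max)
        for r in reads
    ]
    batch = pad_batch(streams)
    return [t.data for t in model.forward(batch, training=False)]


def predict_paired(
    model: TransformerEncoderModel,
    r1: ReadRecord,
    r2: ReadRecord,
    with_cls: Optional[bool] = None,
) -> List[np.ndarray]:
    """Probability vectors per level for a mate pair.

    Scores of the two mates are component-wise averaged, then softmaxed.  A
    mate too short to tokenize is skipped with the other carrying the call;
    if both are unusable a ValueError is raised.
    """
    if with_cls is None:
        with_cls = model.config.reduction == "cls"
    usable = []
    for r in (r1, r2):
        if len(r.sequence) >= model.tokenizer.k:
            usable.append(r)
    if not usable:
        raise ValueError(f"both mates of {r1.id!r} are shorter than k")
    per_level = _batch_scores(model, usable, with_cls)
    return [_softmax(level.mean(axis=0)) for level in per_level]


def classify_reads(
    model: TransformerEncoderModel,
    reads: Iterable[ReadRecord],
    threshold: float = 0.5,
    level_names: Optional[Sequence[str]] = None,
    level_classes: Optional[Sequence[Sequence[str]]] = None,
    paired: bool = False,
    batch_size: int = 256,
) -> Iterator[Prediction]:
    """Classify a read stream; yields one Prediction per read (or per pair).

    With ``paired=True`` the stream must be interleaved (r1, r2, r1, r2, ...)
    and one prediction per fragment is emitted under mate 1's id.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    n_levels = len(model.class_counts)
    names = list(level_names) if level_names else [f"level{i}" for i in range(n_levels)]
    classes = (
        [list(c) for c in level_classes]
        if level_classes
        else [[str(j) for j in range(m)] for m in model.class_counts]
    )
    with_cls = model.config.reduction == "cls"

    def finish(rid: str, probs_per_level: List[np.ndarray]) -> Prediction:
        labels, confs = {}, {}
        for name, cls_list, probs in zip(names, classes, probs_per_level):
            j = int(probs.argmax())
            conf = float(probs[j])
            confs[name] = conf
            labels[name] = cls_list[j] if conf >= threshold else UNCLASSIFIED
        return Prediction(read_id=rid, labels=labels, confidences=confs)

    if paired:
        buf: List[ReadRecord] = []
        for rec in reads:
            buf.append(rec)
            if len(buf) == 2:
                r1, r2 = buf
                buf = []
                yield finish(r1.id, predict_paired(model, r1, r2, with_cls=with_cls))
        if buf:
            raise ValueError("odd number of reads in an interleaved paired stream")
        return

    chunk: List[ReadRecord] = []

    def flush():
        if not chunk:
            return
        per_level = _batch_scores(model, chunk, with_cls)
        probs = [_softmax(level) for level in per_level]
        for i, rec in enumerate(chunk):
            yield finish(rec.id, [p[i] for p in probs])
        chunk.clear()

    for rec in reads:
        chunk.append(rec)
        if len(chunk) >= batch_size:
            yield from flush()
    yield from flush()


def abundance_profile(
    predictions: Iterable[Prediction],
    class_list: Sequence[str],
    level: Optional[str] = None,
) -> AbundanceProfile:
    """Per-class read fractions among classified reads at one level.

    Unclassified reads are excluded from the normalisation but counted in
    ``n_total``.  With no classified reads the profile is all zeros.
    """
    counts = {c: 0 for c in class_list}
    n_classified = 0
    n_total = 0
    for pred in predictions:
        n_total += 1
        lv = level if level is not None else list(pred.labels)[-1]
        label = pred.labels[lv]
        if label == UNCLASSIFIED:
            continue
        n_classified += 1
        counts[label] = counts.get(label, 0) + 1
    if n_classified:
        fractions = {c: counts[c] / n_classified for c in counts}
    else:
        fractions = {c: 0.0 for c in counts}
    return AbundanceProfile(fractions=fractions, n_classified=n_classified, n_total=n_total)
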