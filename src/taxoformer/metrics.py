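"""Read-level precision/recall and profile-level L2 distance.

Read-level metrics follow the thresholded-classifier convention:

    precision = # reads classified correctly / # reads classified
    recall    = # reads classified correctly / # reads

Unclassified reads (confidence below threshold) count only in recall's
denominator, so recall <= precision whenever anything was classified.  With
zero classified reads precision is undefined and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

UNCLASSIFIED = "unclassified"


@dataclass
class MetricsReport:
    """Aggregate and per-class read-level precision/recall."""

    precision: float  # NaN when nothing was classified
    recall: float
    n_reads: int
    n_classified: int
    n_correct: int
    per_class: Dict[str, Dict[str, float]] = field(default_factory=dict)


def precision_recall(
    predictions: Mapping[str, str],
    truths: Mapping[str, str],
) -> MetricsReport:
    """Compare predicted class per read id against ground truth.

    ``predictions`` may assign ``"unclassified"``; every predicted read id
    must exist in ``truths``.
    """
    unknown = set(predictions) - set(truths)
    if unknown:
        raise ValueError(f"predictions for unknown read ids: {sorted(unknown)[:5]}")
    n_reads = len(truths)
    n_classified = 0
    n_correct = 0
    stats: Dict[str, Dict[str, int]] = {}
    for rid, truth in truths.items():
        pred = predictions.get(rid, UNCLASSIFIED)
        s = stats.setdefault(truth, {"total": 0, "classified": 0, "correct": 0})
        s["total"] += 1
        if pred != UNCLASSIFIED:
            n_classified += 1
            s["classified"] += 1
            if pred == truth:
                n_correct += 1
                s["correct"] += 1
    precision = n_correct / n_classified if n_classified else float("nan")
    recall = n_correct / n_reads if n_reads else 0.0
    per_class = {
        c: {
            "precision": s["correct"] / s["classified"] if s["classified"] else float("nan"),
            "recall": s["correct"] / s["total"] if s["total"] else 0.0,
            "total": float(s["total"]),
            "classified": float(s["classified"]),
            "correct": float(s["correct"]),
        }
        for c, s in stats.items()
    }
    return MetricsReport(
        precision=precision,
        recall=recall,
        n_reads=n_reads,
        n_classified=n_classified,
        n_correct=n_correct,
        per_class=per_class,
    )


def l2_distance(
    profile_a: Mapping[str, float],
    profile_b: Mapping[str, float],
) -> float:
    """Euclidean distance between two class-fraction profiles.

    Classes missing from one profile are treated as fraction 0.
    """
    classes = set(profile_a) | set(profile_b)
    diff = np.array([profile_a.get(c, 0.0) - profile_b.get(c, 0.0) for c in classes])
    return float(np.sqrt((diff**2).sum()))
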