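"""Open-set decision rule and metrics.

A sample's *unknown score* is the (unsquared) Euclidean distance from its
embedding to the nearest class prototype; a sample whose score exceeds a
threshold is declared "unknown", otherwise it is assigned the nearest
prototype's class. Metrics follow the unknown-as-positive convention:
unknown-class samples are the positives for both AUROC and F-measure.

AUROC uses the rank (Mann-Whitney) formulation with ties counted 1/2 —
the probability that a random unknown sample scores above a random known
sample — which is threshold-free and invariant under monotone rescaling of
the scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .embedding import PrototypeSet, nearest_prototype

__all__ = [
    "UNKNOWN_LABEL",
    "EvalReport",
    "unknown_score",
    "select_threshold",
    "classify_open_set",
    "compute_auroc",
    "compute_f_measure",
    "evaluate_open_set",
]

#: Sentinel class id used for "predicted unknown".
UNKNOWN_LABEL = -1


def unknown_score(latents: np.ndarray, prototypes: PrototypeSet) -> np.ndarray:
    """Euclidean distance to the nearest prototype; higher = more unknown."""
    _, d2 = nearest_prototype(latents, prototypes)
    return np.sqrt(d2)


def _higher_order_statistic(values: np.ndarray, q: float) -> float:
    """Smallest observed value that is >= a fraction q of the sample."""
    values = np.sort(np.asarray(values, dtype=np.float64))
    if values.size == 0:
        raise ValueError("empty sample")
    idx = max(int(np.ceil(q * values.size)), 1) - 1
    return float(values[min(idx, values.size - 1)])


def select_threshold(
    train_latents: np.ndarray, prototypes: PrototypeSet, percentile: float = 95.0
) -> float:
    """Score threshold = the given percentile of training unknown scores.

    Uses the "higher" order-statistic convention (the smallest observed
    score covering at least the requested fraction), so percentile=100 keeps
    every training sample on the known side.
    """
    if len(np.atleast_2d(train_latents)) == 0:
        raise ValueError("cannot select a threshold from an empty training set")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    scores = unknown_score(train_latents, prototypes)
    if percentile == 0:
        return float(scores.min())
    return _higher_order_statistic(scores, percentile / 100.0)


def classify_open_set(
    latents: np.ndarray, prototypes: PrototypeSet, threshold: float
) -> np.ndarray:
    """Nearest-prototype label where score <= threshold, else UNKNOWN_LABEL."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ids, d2 = nearest_prototype(latents, prototypes)
    preds = ids.copy()
    preds[np.sqrt(d2) > threshold] = UNKNOWN_LABEL
    return preds


def compute_auroc(scores: np.ndarray, is_unknown: np.ndarray) -> float:
    """P(score of a random unknown > score of a random known), ties as 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    is_unknown = np.asarray(is_unknown, dtype=bool)
    n_pos = int(is_unknown.sum())
    n_neg = int((~is_unknown).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one known and one unknown sample")
    ranks = rankdata(scores)  # average ranks implement the tie = 1/2 rule
    u = ranks[is_unknown].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_f_measure(predictions: np.ndarray, is_unknown: np.ndarray) -> float:
    """Binary F1 with predicted-unknown as the positive class; 0 if degenerate."""
    predictions = np.asarray(predictions)
    is_unknown = np.asarray(is_unknown, dtype=bool)
    pred_pos = predictions == UNKNOWN_LABEL
    tp = int((pred_pos & is_unknown).sum())
    fp = int((pred_pos & ~is_unknown).sum())
    fn = int((~pred_pos & is_unknown).sum())
    if tp == 0:
        if fp == 0 and fn == 0:
            warnings.warn("no unknown samples and none predicted; F-measure set to 0")
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Evaluation summary for one trained model on one open-set split."""

    auroc: float
    f_measure: float
    threshold: float
    closed_set_accuracy: float
    n_known: int
    n_unknown: int
    per_class_accuracy: dict[int, float] = field(default_factory=dict)
    scores: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("auroc", "f_measure", "closed_set_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_json(self, path: str | Path | None = None, include_scores: bool = False) -> str:
        payload = {
            "auroc": self.auroc,
            "f_measure": self.f_measure,
            "threshold": self.threshold,
            "closed_set_accuracy": self.closed_set_accuracy,
            "n_known": self.n_known,
            "n_unknown": self.n_unknown,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
        }
        if include_scores:
            payload["scores"] = self.scores
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_open_set(
    train_latents: np.ndarray,
    val_latents: np.ndarray,
    val_labels: np.ndarray,
    unknown_latents: np.ndarray,
    prototypes: PrototypeSet,
    threshold_percentile: float = 95.0,
) -> EvalReport:
    """Full evaluation: threshold from training scores, metrics on val+unknown.

    Closed-set accuracy is nearest-prototype accuracy on the known
    validation samples (no rejection applied); AUROC and F-measure treat the
    unknown-split samples as positives against the known validation set.
    """
    threshold = select_threshold(train_latents, prototypes, threshold_percentile)
    eval_latents = np.concatenate([val_latents, unknown_latents], axis=0)
    is_unknown = np.concatenate(
        [np.zeros(len(val_latents), bool), np.ones(len(unknown_latents), bool)]
    )
    scores = unknown_score(eval_latents, prototypes)
    preds = classify_open_set(eval_latents, prototypes, threshold)

    closed_ids, _ = nearest_prototype(val_latents, prototypes)
    val_labels = np.asarray(val_labels)
    closed_acc = float((closed_ids == val_labels).mean()) if len(val_labels) else 0.0
    per_class = {
        int(c): float((closed_ids[val_labels == c] == c).mean())
        for c in np.unique(val_labels)
    }
    return EvalReport(
        auroc=compute_auroc(scores, is_unknown),
        f_measure=compute_f_measure(preds, is_unknown),
        threshold=threshold,
        closed_set_accuracy=closed_acc,
        n_known=len(val_latents),
        n_unknown=len(unknown_latents),
        per_class_accuracy=per_class,
        scores={
            "score": scores.tolist(),
            "prediction": preds.tolist(),
            "is_unknown": is_unknown.tolist(),
        },
    )
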