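"""Evaluation metrics: one-vs-rest ROC/AUC, PPV and segmental F1.

AUC and precision follow the usual classification conventions (computed per
category one-vs-rest, then macro-averaged).  Segmental F1 at overlap fraction
k (written F1@k; k = 10% is the conventional reporting point for temporal
action segmentation) matches predicted to ground-truth segments of the same
category greedily by intersection-over-union, each ground-truth segment used
at most once, and reports 2·TP / (2·TP + FP + FN) on a 0–100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .inference import EventInterval

__all__ = ["roc_auc", "ppv", "segmental_f1", "MetricReport"]


def roc_auc(scores: np.ndarray, labels, categories) -> dict:
    """One-vs-rest AUC per category plus the macro average.

    ``scores`` is (n, C) with columns ordered like ``categories``.  Categories
    absent from ``labels`` get NaN and are excluded from the macro average.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    out = {}
    for j, cat in enumerate(categories):
        positives = labels == cat
        if positives.all() or not positives.any():
            out[str(cat)] = np.nan
            continue
        out[str(cat)] = float(roc_auc_score(positives, scores[:, j]))
    vals = [v for v in out.values() if not np.isnan(v)]
    out["macro"] = float(np.mean(vals)) if vals else np.nan
    return out


def ppv(predictions, labels, categories=None) -> dict:
    """Precision (positive predictive value) per category plus macro average.

    A category never predicted has undefined precision: reported as NaN with
    a warning, and excluded from the macro average.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if categories is None:
        categories = np.unique(np.concatenate([predictions, labels]))
    out = {}
    for cat in categories:
        predicted = predictions == cat
        if not predicted.any():
            warnings.warn(f"no positive predictions for category {cat!r}; PPV undefined",
                          stacklevel=2)
            out[str(cat)] = np.nan
            continue
        out[str(cat)] = float((labels[predicted] == cat).mean())
    vals = [v for v in out.values() if not np.isnan(v)]
    out["macro"] = float(np.mean(vals)) if vals else np.nan
    return out


def _iou(a: EventInterval, b: EventInterval) -> float:
    inter = max(0.0, min(a.end_s, b.end_s) - max(a.start_s, b.start_s))
    union = max(a.end_s, b.end_s) - min(a.start_s, b.start_s)
    return inter / union if union > 0 else 0.0


def segmental_f1(
    pred_events: list[EventInterval],
    true_events: list[EventInterval],
    overlap_frac: float = 0.10,
) -> float:
    """Segmental F1 at IoU threshold ``overlap_frac``, on a 0–100 scale.

    Each predicted segment greedily claims the unmatched same-category
    ground-truth segment with the highest IoU; a claim below the threshold is
    a false positive, unclaimed ground truth a false negative.
    """
    if not (0.0 < overlap_frac <= 1.0):
        raise ValueError("overlap_frac must lie in (0, 1]")
    matched: set[int] = set()
    tp = fp = 0
    for p in pred_events:
        best_iou, best_idx = 0.0, None
        for i, t in enumerate(true_events):
            if i in matched or t.category != p.category:
                continue
            iou = _iou(p, t)
            if iou > best_iou:
                best_iou, best_idx = iou, i
        if best_idx is not None and best_iou >= overlap_frac:
            matched.add(best_idx)
            tp += 1
        else:
            fp += 1
    fn = len(true_events) - len(matched)
    if tp + fp + fn == 0:
        return 100.0
    return 100.0 * 2 * tp / (2 * tp + fp + fn)


@dataclass
class MetricReport:
    """Per-fold metric values aggregated as mean ± standard deviation."""

    name: str
    per_fold: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))

    @property
    def std(self) -> float:
        return float(np.std(self.per_fold))

    def as_dict(self) -> dict:
        return {"metric": self.name, "mean": self.mean, "std": self.std,
                "per_fold": list(map(float, self.per_fold))}

    def __str__(self) -> str:
        return f"{self.name}: {self.mean:.3f} ± {self.std:.3f} (n={len(self.per_fold)} folds)"


def fold_report(name: str, per_fold) -> MetricReport:
    return MetricReport(name, [float(v) for v in per_fold])
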