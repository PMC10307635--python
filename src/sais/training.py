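"""Video-level Monte Carlo cross-validation and the training workflow.

Splits are drawn at the level of whole case videos so that no clip from a
test video is ever seen during training: each fold independently samples 10%
of the videos as a test set and 10% of the remaining training pool as a
validation set used for epoch selection.  Class balancing downsamples every
category to the size of the rarest one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import TemporalPrototypeClassifier, collate_arrays
from .features import VideoSample

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "make_splits",
    "balance_classes",
    "collate",
    "train_fold",
    "cross_validate",
]


@dataclass(frozen=True)
class SplitSpec:
    """One Monte Carlo fold: disjoint video-id sets covering all videos."""

    fold_id: int
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def __post_init__(self):
        tr, va, te = set(self.train), set(self.val), set(self.test)
        if tr & va or tr & te or va & te:
            raise ValueError("train/val/test video sets must be pairwise disjoint")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (SGD, batch of 8 clips, learning rate 0.1)."""

    batch_size: int = 8
    learning_rate: float = 0.1
    n_epochs: int = 50
    seed: int = 0
    class_balanced: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1 and learning_rate > 0 required")


def make_splits(
    video_ids,
    n_folds: int = 10,
    seed: int = 0,
    test_frac: float = 0.10,
    val_frac: float = 0.10,
) -> list[SplitSpec]:
    """Draw Monte Carlo cross-validation folds at the video level.

    Each fold re-samples independently (folds may overlap in test videos, in
    contrast to partitioned k-fold): ``test_frac`` of the videos form the test
    set and ``val_frac`` of the remaining training pool forms the validation
    set.  Deterministic given ``seed``; fold f uses ``seed + f``.
    """
    ids = sorted(set(map(str, video_ids)))
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 videos for train/val/test splits")
    n_test = max(1, round(test_frac * n))
    n_val = max(1, round(val_frac * (n - n_test)))
    if n - n_test - n_val < 1:
        raise ValueError(f"{n} videos leave no training videos after splitting")
    splits = []
    for fold in range(1, n_folds + 1):
        rng = np.random.default_rng(seed + fold)
        order = list(np.array(ids)[rng.permutation(n)])
        splits.append(
            SplitSpec(
                fold_id=fold,
                test=tuple(sorted(order[:n_test])),
                val=tuple(sorted(order[n_test:n_test + n_val])),
                train=tuple(sorted(order[n_test + n_val:])),
                seed=seed + fold,
            )
        )
    return splits


def write_split_manifest(splits: list[SplitSpec], path: str | Path) -> None:
    rows = [
        {"fold_id": s.fold_id, "role": role, "video_id": vid}
        for s in splits
        for role, vids in (("train", s.train), ("val", s.val), ("test", s.test))
        for vid in vids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def balance_classes(samples, seed: int = 0, key=None):
    """Downsample every category to the size of the rarest category.

    Order of the surviving samples follows the input order; the subset drawn
    within each category is deterministic given ``seed``.
    """
    key = key or (lambda s: s.category)
    by_cat = defaultdict(list)
    for i, s in enumerate(samples):
        by_cat[key(s)].append(i)
    if len(by_cat) < 2:
        raise ValueError("class balancing needs at least two categories")
    m = min(len(v) for v in by_cat.values())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for cat in sorted(by_cat, key=str):
        idx = by_cat[cat]
        chosen = rng.choice(len(idx), size=m, replace=False)
        keep.update(idx[j] for j in chosen)
    return [s for i, s in enumerate(samples) if i in keep]


def collate(batch: list[VideoSample]):
    """Pad a batch of variable-length clips to a common length.

    Returns ``(x_app, x_flow, mask)``; padded rows are zero tensors and the
    boolean mask is False exactly there, so attention never touches them.
    """
    return collate_arrays(batch)


def _partition(samples, split: SplitSpec):
    groups = {"train": [], "val": [], "test": []}
    members = {vid: "train" for vid in split.train}
    members.update({vid: "val" for vid in split.val})
    members.update({vid: "test" for vid in split.test})
    for s in samples:
        role = members.get(s.video_id)
        if role is not None:
            groups[role].append(s)
    return groups["train"], groups["val"], groups["test"]


def train_fold(
    samples: list[VideoSample],
    split: SplitSpec,
    config: TrainConfig = TrainConfig(),
    **estimator_kwargs,
) -> tuple[TemporalPrototypeClassifier, dict]:
    """Train one fold end-to-end and report validation/test metrics.

    The encoder, classification token, positional embeddings, projection head
    and prototypes are all optimised jointly; the epoch with the lowest
    validation loss is kept.
    """
    from . import evaluation

    train, val, test = _partition(samples, split)
    if not train or not val or not test:
        raise ValueError(f"fold {split.fold_id}: a split set has no samples")
    if config.class_balanced:
        train = balance_classes(train, seed=config.seed)
    clf = TemporalPrototypeClassifier(
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        n_epochs=config.n_epochs,
        random_state=config.seed + split.fold_id,
        **estimator_kwargs,
    )
    y = [s.category for s in train]
    y_val = [s.category for s in val]
    clf.fit(train, y, X_val=val, y_val=y_val)

    metrics = {"fold_id": split.fold_id, "loss_curve": clf.loss_curve_,
               "val_loss_curve": clf.val_loss_curve_, "best_epoch": clf.best_epoch_}
    val_scores = clf.predict_proba(val)
    metrics["val_auc"] = evaluation.roc_auc(val_scores, y_val, clf.classes_)["macro"]
    test_scores = clf.predict_proba(test)
    y_test = [s.category for s in test]
    metrics["test_auc"] = evaluation.roc_auc(test_scores, y_test, clf.classes_)["macro"]
    metrics["test_scores"] = test_scores
    metrics["test_labels"] = y_test
    return clf, metrics


def cross_validate(
    samples: list[VideoSample],
    n_folds: int = 10,
    config: TrainConfig = TrainConfig(),
    **estimator_kwargs,
) -> tuple[list[TemporalPrototypeClassifier], list[dict]]:
    """Monte Carlo cross-validation: train one model per fold."""
    splits = make_splits(sorted({s.video_id for s in samples}),
                         n_folds=n_folds, seed=config.seed)
    models, reports = [], []
    for split in splits:
        clf, metrics = train_fold(samples, split, config, **estimator_kwargs)
        models.append(clf)
        reports.append(metrics)
    return models, reports
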