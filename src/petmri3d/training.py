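"""Stratified cross-validated ensemble training.

Five-fold stratified splitting with staggered remainder allocation,
per-fold training with early stopping on validation AUC, balanced
threshold selection on the validation scores, and ensemble assembly
whose decision threshold is the mean of the member thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from petmri3d.metrics import confusion, roc_auc, sens_spec_acc
from petmri3d.model import (
    ModelConfig,
    ModelHandle,
    build_model,
    focal_loss,
    focal_loss_grad,
    make_optimiser,
)
from petmri3d.preprocess import TrainingTensor, augment

__all__ = [
    "FoldSplit", "FoldModel", "Ensemble", "TrainConfig",
    "stratified_folds", "select_threshold", "train_fold", "build_ensemble",
    "train_cv", "ensemble_forward",
]


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]


@dataclass
class FoldModel:
    model: ModelHandle
    threshold: float
    best_epoch: int = 0
    val_metrics: dict[str, float] = field(default_factory=dict)


@dataclass
class Ensemble:
    """Five fold-trained models; the ensemble probability is the mean of
    member probabilities and the decision threshold the arithmetic mean
    of member thresholds."""

    members: list[FoldModel]
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        fps = {m.model.fingerprint for m in self.members}
        if len(fps) != 1:
            raise ValueError(f"ensemble members have mismatched architectures: {fps}")
        self.threshold = float(np.mean([m.threshold for m in self.members]))


@dataclass(frozen=True)
class TrainConfig:
    """Per-fold training schedule.

    ``patience`` is the number of consecutive epochs without a new best
    validation AUC tolerated before stopping (0 means stop after the
    first non-improving epoch). Augmentation is applied to the training
    side only, after splitting, so augmented copies of one case never
    straddle a fold boundary.
    """

    epochs: int = 100
    batch_size: int = 8
    patience: int = 10
    augment: bool = True
    seed: int = 0


def stratified_folds(
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> list[FoldSplit]:
    """Stratified k-fold partition with staggered remainder allocation.

    Within each class, members are shuffled and dealt into k folds of
    near-equal size; the per-class remainder goes to folds starting at
    an offset equal to the class rank (positives first), rotating. With
    101 positives + 101 negatives and k=5 this yields validation folds
    of 41, 41, 40, 40, 40 cases with positives 21,20,20,20,20 and
    negatives 20,21,20,20,20 — each fold's class ratio within one case
    of the global ratio.
    """
    labels = np.asarray(labels)
    if ids is None:
        ids = [f"case_{i:04d}" for i in range(len(labels))]
    ids = np.asarray(ids, dtype=object)
    rng = np.random.Generator(np.random.PCG64(seed))
    fold_val: list[list[str]] = [[] for _ in range(k)]
    classes = sorted(np.unique(labels), reverse=True)  # positives first
    for rank, cls in enumerate(classes):
        members = ids[labels == cls].copy()
        if len(members) < k:
            raise ValueError(f"class {cls} has {len(members)} members < k={k}")
        rng.shuffle(members)
        base, rem = divmod(len(members), k)
        sizes = [base] * k
        for t in range(rem):
            sizes[(rank + t) % k] += 1
        pos = 0
        for f in range(k):
            fold_val[f].extend(members[pos : pos + sizes[f]])
            pos += sizes[f]
    all_ids = set(ids)
    return [
        FoldSplit(
            fold_id=f + 1,
            train_ids=tuple(sorted(all_ids - set(fold_val[f]))),
            val_ids=tuple(fold_val[f]),
        )
        for f in range(k)
    ]


def _confusion_at(scores: np.ndarray, labels: np.ndarray, thr: float):
    return confusion((scores >= thr).astype(int), labels)


def threshold_candidates(scores: Sequence[float]) -> np.ndarray:
    """Midpoints of adjacent sorted unique scores (the score itself when
    there is only one unique value)."""
    u = np.unique(np.asarray(scores, dtype=float))
    if len(u) == 1:
        return u
    return (u[1:] + u[:-1]) / 2.0


def select_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    criterion: str = "balanced",
) -> float:
    """Pick the decision cut-off balancing sensitivity and specificity.

    Among the candidate thresholds, ``balanced`` maximises
    ``min(sensitivity, specificity)`` (ties broken by higher
    sensitivity, then by lower threshold); ``youden`` maximises
    ``sensitivity + specificity - 1`` with the same tie-breaks. The
    decision rule is ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("select_threshold requires both classes present")
    if criterion not in ("balanced", "youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    best = None
    for thr in threshold_candidates(scores):
        c = _confusion_at(scores, labels, thr)
        sens = c.TP / (c.TP + c.FN)
        spec = c.TN / (c.TN + c.FP)
        obj = min(sens, spec) if criterion == "balanced" else sens + spec - 1
        key = (obj, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return float(best[1])


def _stack(tensors: Sequence[TrainingTensor]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([t.data for t in tensors]).astype(np.float32)
    y = np.array([t.label for t in tensors], dtype=np.float64)
    return x, y


def _val_scores(model: ModelHandle, tensors: Sequence[TrainingTensor]) -> np.ndarray:
    from petmri3d.model import forward
    x, _ = _stack(tensors)
    return np.asarray(forward(model, x), dtype=float)


def train_fold(
    split: FoldSplit,
    data: Mapping[str, TrainingTensor],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> FoldModel:
    """Train one fold model with early stopping on validation AUC.

    Validation AUC is monitored each epoch; after ``patience``
    consecutive epochs without improvement, training stops and the
    best-epoch parameters are restored. The decision threshold is then
    selected on the restored model's validation scores. Validation data
    is never augmented.
    """
    train_tensors = [data[i] for i in split.train_ids]
    val_tensors = [data[i] for i in split.val_ids]
    if not train_tensors:
        raise ValueError(f"fold {split.fold_id}: empty training side")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([train_config.seed, split.fold_id]))
    )
    if train_config.augment:
        train_tensors = augment(train_tensors, rng)
    x_train, y_train = _stack(train_tensors)
    y_val = np.array([t.label for t in val_tensors], dtype=int)

    model = build_model(model_config)
    opt = make_optimiser(model)
    n = len(x_train)
    best_auc, best_epoch, best_state = -np.inf, 0, model.net.state_dict()
    since_best = 0
    epochs_run = 0
    for epoch in range(1, train_config.epochs + 1):
        epochs_run = epoch
        order = rng.permutation(n)
        for lo in range(0, n, train_config.batch_size):
            idx = order[lo : lo + train_config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.net.zero_grad()
            probs = model.net.forward(
                np.moveaxis(xb, -1, 1).astype(np.float32), training=True
            )
            dprob = focal_loss_grad(probs, yb, model_config) / len(idx)
            model.net.backward(dprob.astype(np.float32))
            opt.step()
            model.steps += 1
        scores = _val_scores(model, val_tensors)
        auc = roc_auc(scores, y_val).auc
        if auc > best_auc:
            best_auc, best_epoch = auc, epoch
            best_state = model.net.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best > train_config.patience:
                break
    model.net.load_state_dict(best_state)
    scores = _val_scores(model, val_tensors)
    thr = select_threshold(scores, y_val)
    c = _confusion_at(scores, y_val, thr)
    sens, spec, acc = sens_spec_acc(c)
    return FoldModel(
        model=model,
        threshold=thr,
        best_epoch=best_epoch,
        val_metrics={"accuracy": acc, "sensitivity": sens, "specificity": spec,
                     "auc": best_auc, "TN": c.TN, "FP": c.FP, "FN": c.FN, "TP": c.TP,
                     "epochs_run": epochs_run},
    )


def build_ensemble(members: Sequence[FoldModel], k: int = 5) -> Ensemble:
    """Assemble exactly ``k`` fold models into an ensemble."""
    if len(members) != k:
        raise ValueError(f"expected exactly {k} members, got {len(members)}")
    return Ensemble(members=list(members))


def ensemble_forward(ensemble: Ensemble, tensor: np.ndarray) -> float:
    """Mean of member probabilities for one (x, y, z, c) tensor."""
    from petmri3d.model import forward
    return float(np.mean([forward(m.model, tensor) for m in ensemble.members]))


def train_cv(
    data: Mapping[str, TrainingTensor],
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
) -> tuple[Ensemble, list[FoldSplit]]:
    """Full stratified k-fold run returning the ensemble and the splits."""
    ids = sorted(data)
    labels = [data[i].label for i in ids]
    splits = stratified_folds(labels, k=k, seed=train_config.seed, ids=ids)
    members = []
    for split in splits:
        fold_cfg = ModelConfig(**{**model_config.__dict__,
                                  "seed": model_config.seed + split.fold_id})
        members.append(train_fold(split, data, fold_cfg, train_config))
    return build_ensemble(members, k=k), splits
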