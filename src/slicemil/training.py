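"""Weighted-sampling training loop with cosine-annealed Adam, early
stopping on validation exam-level AUC, and stratified k-fold CV.

Every stochastic component (fold assignment, sampler, parameter init) draws
from a named substream of one master seed, so a run is reproducible
end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import (
    ModelConfig,
    SequenceClassifier,
    build_model,
    semiweak_loss_graph,
)
from .nn import Adam
from .preprocess import AugmentConfig, ProcessedSequence, augment
from .supervision import ClassWeights, build_supervision
from .evaluation import PredictionSet, roc_auc

__all__ = [
    "TrainingConfig",
    "FoldSplit",
    "make_folds",
    "cosine_lr",
    "weighted_sampler",
    "train_fold",
    "train_cv",
    "predict_cohort",
]


@dataclass(frozen=True)
class TrainingConfig:
    epochs_max: int = 30
    lr_init: float = 1e-4
    lr_min: float = 1e-6
    t_max: int = 30
    batch_size: int = 16
    early_stop_patience: int = 5
    k_folds: int = 5
    seed: int = 0
    lambda_slice: float = 1.0
    proportion: float = 1.0
    model: ModelConfig = field(default_factory=ModelConfig)
    augment: AugmentConfig | None = None
    grad_clip: float | None = None

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must be <= lr_init")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class FoldSplit:
    """exam_id -> fold index, stratified by exam label."""

    assignments: dict[str, int]
    k: int

    def fold_of(self, exam_id: str) -> int:
        return self.assignments[exam_id]

    def val_ids(self, fold: int) -> list[str]:
        return [e for e, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [e for e, f in self.assignments.items() if f != fold]


def make_folds(cohort: list[ProcessedSequence], k: int, seed: int) -> FoldSplit:
    labels = np.array([s.exam_label for s in cohort])
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"k={k} exceeds the count of class {cls}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in val_idx:
            assignments[cohort[i].exam_id] = fold
    return FoldSplit(assignments=assignments, k=k)


def cosine_lr(epoch: int, config: TrainingConfig) -> float:
    """lr = lr_min + (lr_init - lr_min) * (1 + cos(pi * epoch / t_max)) / 2."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr_min + 0.5 * (config.lr_init - config.lr_min) * (
        1.0 + math.cos(math.pi * epoch / config.t_max)
    )


def weighted_sampler(
    cohort: list[ProcessedSequence],
    weights: ClassWeights,
    rng: np.random.Generator,
    n_draws: int | None = None,
) -> list[str]:
    """Sample exam ids with replacement, probability proportional to the
    class weight of each exam; one epoch draws `len(cohort)` exams."""
    w = np.array(
        [weights.w_pos if s.exam_label == 1 else weights.w_neg for s in cohort]
    )
    p = w / w.sum()
    n = len(cohort) if n_draws is None else n_draws
    idx = rng.choice(len(cohort), size=n, replace=True, p=p)
    return [cohort[i].exam_id for i in idx]


def _cohort_weights(cohort: list[ProcessedSequence]) -> ClassWeights:
    n_pos = sum(s.exam_label for s in cohort)
    n_neg = len(cohort) - n_pos
    from .supervision import class_weights

    return class_weights(len(cohort), n_pos, n_neg)


def predict_cohort(
    model: SequenceClassifier, cohort: list[ProcessedSequence]
) -> PredictionSet:
    """Exam-level probabilities for a list of sequences (eval mode).

    Exams of equal depth are batched through one forward pass.
    """
    from .autodiff import no_grad

    scores, labels = {}, {}
    by_depth: dict[int, list[ProcessedSequence]] = {}
    for seq in cohort:
        by_depth.setdefault(seq.depth, []).append(seq)
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            for group in by_depth.values():
                for start in range(0, len(group), 8):  # bound peak memory
                    chunk = group[start : start + 8]
                    frames = np.stack(
                        [np.asarray(s.frames, dtype=np.float64) for s in chunk]
                    )
                    _, exam_logits, _ = model.forward_batch(frames)
                    probs = 1.0 / (1.0 + np.exp(-exam_logits.data))
                    for seq, prob in zip(chunk, probs):
                        scores[seq.exam_id] = float(prob)
                        labels[seq.exam_id] = seq.exam_label
    finally:
        if was_training:
            model.train()
    return PredictionSet.from_dicts(scores, labels)


def train_fold(
    train_set: list[ProcessedSequence],
    val_set: list[ProcessedSequence],
    config: TrainingConfig,
    seed: int | None = None,
) -> tuple[SequenceClassifier, list[dict]]:
    """Optimize the semi-weak objective on `train_set`, early-stopping on
    validation exam AUC; returns the best-AUC model and per-epoch history."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 0])
    sampler_rng = np.random.default_rng([seed, 1])
    aug_rng = np.random.default_rng([seed, 2])
    model = build_model(config.model, rng)
    optimizer = Adam(model.parameters(), lr=config.lr_init)
    weights = _cohort_weights(train_set)
    by_id = {s.exam_id: s for s in train_set}
    supervision = {
        s.exam_id: build_supervision(_as_record_like(s), config.proportion)
        for s in train_set
    }

    best_state, best_auc, best_epoch = None, -np.inf, -1
    history: list[dict] = []
    for epoch in range(config.epochs_max):
        lr = cosine_lr(epoch, config)
        optimizer.lr = lr
        model.train()
        epoch_ids = weighted_sampler(train_set, weights, sampler_rng)
        losses = []
        for start in range(0, len(epoch_ids), config.batch_size):
            batch = [by_id[e] for e in epoch_ids[start : start + config.batch_size]]
            if config.augment is not None:
                batch = [augment(s, config.augment, aug_rng) for s in batch]
            frames = np.stack([np.asarray(s.frames, dtype=np.float64) for s in batch])
            exam_labels = np.array([s.exam_label for s in batch], dtype=float)
            slice_labels = np.stack([s.slice_labels for s in batch]).astype(float)
            masks = np.stack([supervision[s.exam_id].mask for s in batch])
            slice_logits, exam_logits, _ = model.forward_batch(frames)
            loss = semiweak_loss_graph(
                slice_logits,
                exam_logits,
                exam_labels,
                slice_labels,
                masks,
                config.lambda_slice,
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            if config.grad_clip is not None:
                _clip_grad_norm(model, config.grad_clip)
            optimizer.step()
            losses.append(loss.item())
        val_preds = predict_cohort(model, val_set)
        val_auc = roc_auc(val_preds)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "val_auc": float(val_auc),
            }
        )
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_state = model.state_dict()
        if epoch - best_epoch >= config.early_stop_patience:
            break
    assert best_state is not None
    model.load_state_dict(best_state)
    return model, history


def _clip_grad_norm(model: SequenceClassifier, max_norm: float):
    """Scale all gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    params = [p for p in model.parameters() if p.grad is not None]
    for p in params:
        total += float((p.grad**2).sum())
    norm = math.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            p.grad *= scale


def _as_record_like(seq: ProcessedSequence):
    """Adapter: build_supervision accepts a VolumeRecord or a depth; give it
    enough of a record to carry the exam id and label."""
    from .synthetic import VolumeRecord

    return VolumeRecord(
        exam_id=seq.exam_id,
        volume=np.zeros((seq.depth, 1, 1)),
        mask=np.ones((seq.depth, 1, 1)),
        slice_labels=np.asarray(seq.slice_labels),
        exam_label=seq.exam_label,
        subtype=seq.subtype,
    )


def train_cv(
    cohort: list[ProcessedSequence], config: TrainingConfig
) -> list[tuple[SequenceClassifier, list[dict], int]]:
    """Stratified k-fold CV; fold k trains on the other folds and validates
    on fold k, with fold seed = master seed + fold index."""
    folds = make_folds(cohort, config.k_folds, config.seed)
    by_id = {s.exam_id: s for s in cohort}
    results = []
    for fold in range(config.k_folds):
        train_set = [by_id[e] for e in folds.train_ids(fold)]
        val_set = [by_id[e] for e in folds.val_ids(fold)]
        model, history = train_fold(
            train_set, val_set, config, seed=config.seed + fold
        )
        results.append((model, history, fold))
    return results
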