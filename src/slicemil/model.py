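"""Attention + bidirectional-recurrent sequence classifier.

Architecture: a pluggable per-slice feature extractor (backbone) maps each
3-channel slice image to a feature vector; features pass through batch
normalization, a stack of three bidirectional LSTM layers aggregating along
the slice axis, per-slice sigmoid heads on the recurrent hidden states, and
gated softmax attention pooling which — concatenated with a slice-wise max
pool — feeds an exam-level sigmoid head.

The semi-weak objective is

    L = BCE(exam_prob, exam_label)
        + lambda_slice * mean_{i: mask_i = 1} BCE(slice_prob_i, slice_label_i)

so masked slices contribute neither value nor gradient; with an all-zero
mask the objective reduces exactly to the weak (exam-only) learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, stack
from .preprocess import ProcessedSequence

__all__ = [
    "ModelConfig",
    "ModelOutput",
    "TinyCNNBackbone",
    "MeanFeatureBackbone",
    "SequenceClassifier",
    "build_model",
    "semiweak_loss",
    "semiweak_loss_graph",
    "BCE_EPS",
]

BCE_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny_cnn"
    feature_dim: int = 64
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    rnn_hidden: int = 128
    rnn_layers: int = 3
    attention_dim: int = 64
    lambda_slice: float = 1.0


@dataclass
class ModelOutput:
    """Per-slice probabilities, exam probability, and attention weights."""

    slice_probs: np.ndarray  # (D,) in (0, 1)
    exam_prob: float  # in (0, 1)
    attention_weights: np.ndarray  # (D,), nonnegative, sums to 1

    def __post_init__(self):
        if not np.all(np.isfinite(self.slice_probs)) or not np.isfinite(self.exam_prob):
            raise ValueError("non-finite probabilities")
        if abs(self.attention_weights.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must sum to 1")


class TinyCNNBackbone(nn.Module):
    """Three stride-2 conv blocks + global average & max pooling + linear
    projection.

    Max pooling is concatenated with average pooling so that small, highly
    localized structures (a lesion occupying a few pixels) survive the
    global pool instead of being diluted. Small enough to train a full
    pipeline on one CPU; satisfies the backbone contract (deterministic in
    eval mode, fixed feature_dim). A larger pretrained extractor can be
    swapped in through the same interface.
    """

    def __init__(self, feature_dim: int, rng: np.random.Generator, channels=(8, 16, 32)):
        super().__init__()
        c1, c2, c3 = channels
        self.conv1 = nn.Conv2d(3, c1, 3, rng, stride=2, padding=1)
        self.conv2 = nn.Conv2d(c1, c2, 3, rng, stride=2, padding=1)
        self.conv3 = nn.Conv2d(c2, c3, 3, rng, stride=2, padding=1)
        self.proj = nn.Linear(2 * c3, feature_dim, rng)
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> Tensor:
        """(N, 3, H, W) -> (N, feature_dim)."""
        from .autodiff import concat

        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        n, c = h.shape[0], h.shape[1]
        flat = h.reshape(n, c, h.shape[2] * h.shape[3])
        avg = flat.mean(axis=2)
        mx = flat.max_(axis=2)
        return self.proj(concat([avg, mx], axis=1))


class MeanFeatureBackbone(nn.Module):
    """Trivial backbone: per-channel mean/std intensity features, projected.

    Useful for smoke tests where convolution cost is unwanted.
    """

    def __init__(self, feature_dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(6, feature_dim, rng)
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=(2, 3))
        var = ((x - x.mean(axis=(2, 3), keepdims=True)) ** 2).mean(axis=(2, 3))
        from .autodiff import concat

        return self.proj(concat([mean, (var + 1e-8) ** 0.5], axis=1))


_BACKBONES = {"tiny_cnn": TinyCNNBackbone, "mean_features": MeanFeatureBackbone}


class SequenceClassifier(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        if config.backbone == "tiny_cnn":
            self.backbone = TinyCNNBackbone(
                config.feature_dim, rng, channels=config.conv_channels
            )
        elif config.backbone == "mean_features":
            self.backbone = MeanFeatureBackbone(config.feature_dim, rng)
        else:
            raise ValueError(f"unknown backbone {config.backbone!r}")
        self.bn = nn.BatchNorm1d(config.feature_dim)
        self.rnn = nn.BiLSTM(
            config.feature_dim, config.rnn_hidden, config.rnn_layers, rng
        )
        hidden = self.rnn.output_size
        self.slice_head = nn.Linear(hidden, 1, rng)
        self.attention = nn.AttentionPool(hidden, config.attention_dim, rng)
        # exam head reads the attention-pooled state concatenated with the
        # slice-wise max-pooled state, so peak slice evidence reaches it
        # directly even when attention is diffuse
        self.exam_head = nn.Linear(2 * hidden, 1, rng)

    def forward_batch(self, frames: np.ndarray):
        """(B, D, 3, H, W) -> (slice_logits (B, D), exam_logits (B,), attn (B, D))."""
        b, d = frames.shape[:2]
        x = Tensor(frames.reshape(b * d, *frames.shape[2:]))
        feats = self.bn(self.backbone(x))  # (B*D, F)
        f = feats.shape[1]
        per_slice = feats.reshape(b, d, f).transpose(1, 0, 2)  # (D, B, F)
        hidden_seq = self.rnn([per_slice[i] for i in range(d)])  # D x (B, 2H)
        hidden = stack(hidden_seq, axis=1)  # (B, D, 2H)
        slice_logits = self.slice_head(
            hidden.reshape(b * d, hidden.shape[2])
        ).reshape(b, d)
        pooled, attn = self.attention(hidden)
        peak = hidden.max_(axis=1)  # (B, 2H) slice-wise max pool
        from .autodiff import concat

        exam_logits = self.exam_head(concat([pooled, peak], axis=1)).reshape(b)
        return slice_logits, exam_logits, attn

    def predict(self, sequence: ProcessedSequence) -> ModelOutput:
        """Inference on one exam."""
        from .autodiff import no_grad

        was_training = self.training
        self.eval()
        try:
            with no_grad():
                slice_logits, exam_logits, attn = self.forward_batch(
                    np.asarray(sequence.frames, dtype=np.float64)[None]
                )
        finally:
            if was_training:
                self.train()
        return ModelOutput(
            slice_probs=1.0 / (1.0 + np.exp(-slice_logits.data[0])),
            exam_prob=float(1.0 / (1.0 + np.exp(-exam_logits.data[0]))),
            attention_weights=attn.data[0],
        )


def build_model(config: ModelConfig, rng: np.random.Generator) -> SequenceClassifier:
    return SequenceClassifier(config, rng)


def _bce(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def semiweak_loss(
    output: ModelOutput,
    exam_label: int,
    slice_labels: np.ndarray,
    mask: np.ndarray,
    lambda_slice: float = 1.0,
) -> float:
    """Reference (numpy) semi-weak objective for a single exam."""
    if lambda_slice < 0:
        raise ValueError("lambda_slice must be >= 0")
    slice_labels = np.asarray(slice_labels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(output.slice_probs) or len(slice_labels) != len(mask):
        raise ValueError("mask/slice_labels length mismatch")
    loss = float(_bce(np.asarray(output.exam_prob), float(exam_label)))
    if mask.any():
        loss += lambda_slice * float(
            _bce(output.slice_probs[mask], slice_labels[mask]).mean()
        )
    return loss


def semiweak_loss_graph(
    slice_logits: Tensor,
    exam_logits: Tensor,
    exam_labels: np.ndarray,
    slice_labels: np.ndarray,
    masks: np.ndarray,
    lambda_slice: float = 1.0,
) -> Tensor:
    """Differentiable batched objective, mean over the batch.

    slice_logits (B, D), exam_logits (B,); masks (B, D) select the slices
    whose labels are visible; the slice term is averaged over visible slices
    *per exam* and contributes nothing for all-masked exams.
    """
    b = exam_logits.shape[0]
    exam_p = exam_logits.sigmoid().clamp(BCE_EPS, 1.0 - BCE_EPS)
    y = Tensor(np.asarray(exam_labels, dtype=float))
    exam_bce = -(y * exam_p.log() + (1.0 - y) * (1.0 - exam_p).log())
    total = exam_bce.mean()
    masks = np.asarray(masks, dtype=float)
    if lambda_slice > 0 and masks.any():
        slice_p = slice_logits.sigmoid().clamp(BCE_EPS, 1.0 - BCE_EPS)
        ys = Tensor(np.asarray(slice_labels, dtype=float))
        bce = -(ys * slice_p.log() + (1.0 - ys) * (1.0 - slice_p).log())
        m = Tensor(masks)
        per_exam_count = np.maximum(masks.sum(axis=1), 1.0)  # avoid 0-division
        per_exam = (bce * m).sum(axis=1) / Tensor(per_exam_count)
        # average the slice term over exams that have visible slices
        n_with = float((masks.sum(axis=1) > 0).sum())
        total = total + (lambda_slice / n_with) * per_exam.sum()
    return total
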