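"""Semi-weak labeling machinery.

Slice-level supervision is controlled by a single proportion p: a fraction p
of each exam's slice labels stays visible to the loss, the rest are masked.
Visible slices are sampled *evenly* across the lung extent — the way an
annotator asked to label a quarter of an exam would spread their effort —
by rounding an endpoint-inclusive linspace. p = 0 is weak supervision (exam
labels only), p = 1 strong supervision (every slice labeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import VolumeRecord
from .util import round_half_up

__all__ = [
    "SliceSupervision",
    "ClassWeights",
    "validate_labels",
    "select_labeled_slices",
    "build_supervision",
    "class_weights",
]


@dataclass(frozen=True)
class SliceSupervision:
    """Which slice labels are visible at proportion p, as indices and mask."""

    exam_id: str
    labeled_indices: tuple[int, ...]
    proportion: float
    mask: np.ndarray  # (D,) uint8; 1 = slice loss applied

    def __post_init__(self):
        if set(self.labeled_indices) != set(np.flatnonzero(self.mask).tolist()):
            raise ValueError("mask and labeled_indices disagree")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-prevalence sampling weights: w_c = n_total / n_c."""

    w_pos: float
    w_neg: float

    def rounded(self, decimals: int = 2) -> tuple[float, float]:
        return (round(self.w_pos, decimals), round(self.w_neg, decimals))


REASON_POS_NO_SLICES = "positive exam, no positive slices"
REASON_NEG_WITH_SLICES = "negative exam, positive slices"


def validate_labels(
    cohort: list[VolumeRecord],
) -> tuple[list[VolumeRecord], list[tuple[str, str]]]:
    """Enforce exam_label == max(slice_labels); offenders are excluded.

    Returns the clean cohort and an exclusion report of (exam_id, reason).
    """
    clean, report = [], []
    for rec in cohort:
        has_pos_slice = bool(rec.slice_labels.max(initial=0))
        if rec.exam_label == 1 and not has_pos_slice:
            report.append((rec.exam_id, REASON_POS_NO_SLICES))
        elif rec.exam_label == 0 and has_pos_slice:
            report.append((rec.exam_id, REASON_NEG_WITH_SLICES))
        else:
            clean.append(rec)
    if not clean:
        raise ValueError("empty cohort after label-consistency filtering")
    return clean, report


def select_labeled_slices(n_slices: int, proportion: float) -> np.ndarray:
    """Evenly spaced slice indices retaining their labels at proportion p.

    n = round_half_up(p * n_slices); indices = round_half_up of an
    endpoint-inclusive linspace over [0, n_slices - 1]. For n >= 2 both
    extremes are included and consecutive gaps differ by at most one.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must be in [0, 1]")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    n = min(max(round_half_up(proportion * n_slices), 0), n_slices)
    if n == 0:
        return np.array([], dtype=int)
    positions = np.linspace(0, n_slices - 1, n)
    return np.array([round_half_up(p) for p in positions], dtype=int)


def build_supervision(
    record: VolumeRecord | int,
    proportion: float,
    exam_id: str = "",
    reveal_negative_slices: bool = False,
) -> SliceSupervision:
    """Loss mask for one exam at proportion p.

    By default the same masking applies to negative exams even though their
    slice labels are implied by the consistency rule — that models the
    annotation-cost scenario. `reveal_negative_slices` reveals all slices of
    negative exams instead.
    """
    if isinstance(record, VolumeRecord):
        depth = len(record.slice_labels)
        exam_id = record.exam_id
        is_negative = record.exam_label == 0
    else:
        depth = int(record)
        is_negative = False
    if reveal_negative_slices and is_negative:
        indices = np.arange(depth)
    else:
        indices = select_labeled_slices(depth, proportion)
    mask = np.zeros(depth, dtype=np.uint8)
    mask[indices] = 1
    return SliceSupervision(
        exam_id=exam_id,
        labeled_indices=tuple(int(i) for i in indices),
        proportion=float(proportion),
        mask=mask,
    )


def class_weights(n_total: int, n_pos: int, n_neg: int) -> ClassWeights:
    """w_pos = n_total / n_pos, w_neg = n_total / n_neg (inverse prevalence)."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be nonempty")
    if n_pos + n_neg != n_total:
        raise ValueError("n_pos + n_neg must equal n_total")
    return ClassWeights(w_pos=n_total / n_pos, w_neg=n_total / n_neg)
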