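"""Exam-level statistical evaluation.

Protocol: average predictions across CV models, pick the operating threshold
by Youden's J (TPR - FPR) on a tuning split, apply it frozen to test and
external splits, and report AUC with a DeLong confidence interval, the
confusion counts at the threshold, derived diagnostic metrics with binomial
confidence intervals, and paired DeLong tests between models.

AUC follows the Mann-Whitney convention (ties count 1/2); the decision rule
is "positive iff score >= threshold".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .util import round_report

__all__ = [
    "PredictionSet",
    "ConfusionCounts",
    "EvaluationReport",
    "ensemble_predictions",
    "roc_auc",
    "youden_threshold",
    "apply_threshold",
    "confusion_metrics",
    "delong_test",
    "auc_ci",
    "binomial_ci",
    "evaluate",
    "subtype_reports",
]


@dataclass(frozen=True)
class PredictionSet:
    """Aligned exam ids, scores in [0, 1], and binary labels."""

    exam_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        if not (len(self.exam_ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @classmethod
    def from_dicts(
        cls, scores: dict[str, float], labels: dict[str, int], provenance: str = ""
    ) -> "PredictionSet":
        ids = tuple(sorted(scores))
        if set(ids) - set(labels):
            raise ValueError("every scored exam needs a label")
        return cls(
            exam_ids=ids,
            scores=np.array([scores[e] for e in ids], dtype=float),
            labels=np.array([labels[e] for e in ids], dtype=int),
            provenance=provenance,
        )

    def subset(self, keep_ids: set[str], provenance: str = "") -> "PredictionSet":
        idx = [i for i, e in enumerate(self.exam_ids) if e in keep_ids]
        return PredictionSet(
            exam_ids=tuple(self.exam_ids[i] for i in idx),
            scores=self.scores[idx],
            labels=self.labels[idx],
            provenance=provenance or self.provenance,
        )

    def _check_two_classes(self):
        if len(np.unique(self.labels)) < 2:
            raise ValueError("need at least one positive and one negative exam")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class EvaluationReport:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    metric_cis: dict[str, tuple[float, float] | None]
    provenance: str = ""


def ensemble_predictions(fold_predictions: list[PredictionSet]) -> PredictionSet:
    """Per-exam arithmetic mean of scores across CV folds."""
    first = fold_predictions[0]
    for other in fold_predictions[1:]:
        if other.exam_ids != first.exam_ids or not np.array_equal(
            other.labels, first.labels
        ):
            raise ValueError("fold predictions must share exams and labels")
    mean_scores = np.mean([p.scores for p in fold_predictions], axis=0)
    return PredictionSet(
        exam_ids=first.exam_ids,
        scores=mean_scores,
        labels=first.labels,
        provenance="ensemble",
    )


def roc_auc(preds: PredictionSet) -> float:
    """Mann-Whitney AUC (ties count half)."""
    preds._check_two_classes()
    return float(roc_auc_score(preds.labels, preds.scores))


def youden_threshold(preds: PredictionSet) -> float:
    """Threshold maximizing J = TPR - FPR over the observed unique scores,
    under the rule "positive iff score >= t"; ties -> smallest threshold."""
    preds._check_two_classes()
    candidates = np.unique(preds.scores)
    pos = preds.scores[preds.labels == 1]
    neg = preds.scores[preds.labels == 0]
    tpr = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= candidates[:, None]).mean(axis=1)
    j = tpr - fpr
    return float(candidates[np.argmax(j)])  # argmax takes the first (smallest t)


def apply_threshold(preds: PredictionSet, threshold: float) -> ConfusionCounts:
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred_pos = preds.scores >= threshold
    pos = preds.labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & pos)),
        fn=int(np.sum(~pred_pos & pos)),
        tn=int(np.sum(~pred_pos & ~pos)),
        fp=int(np.sum(pred_pos & ~pos)),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Standard diagnostic metrics, rounded half-up to 3 decimals.

    A metric whose denominator is zero is reported as None (undefined).
    """

    def ratio(num: int, den: int) -> float | None:
        return round_report(num / den) if den > 0 else None

    c = counts
    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


# ------------------------------------------------------------------ DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Fast (midrank) DeLong structural components.

    Returns (auc, v10, v01): per-positive and per-negative placement values
    whose means are the AUC.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_test(
    preds_a: PredictionSet, preds_b: PredictionSet
) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same exams.

    Returns (auc_a, auc_b, z, p_two_sided); identical score vectors give
    p = 1.0 by convention.
    """
    if preds_a.exam_ids != preds_b.exam_ids or not np.array_equal(
        preds_a.labels, preds_b.labels
    ):
        raise ValueError("paired test requires identical exams and labels")
    preds_a._check_two_classes()
    auc_a, v10_a, v01_a = _delong_components(preds_a.scores, preds_a.labels)
    auc_b, v10_b, v01_b = _delong_components(preds_b.scores, preds_b.labels)
    if np.allclose(preds_a.scores, preds_b.scores):
        return float(auc_a), float(auc_b), 0.0, 1.0
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        return float(auc_a), float(auc_b), 0.0, 1.0
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0 or not np.isfinite(var):
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def auc_ci(preds: PredictionSet, level: float = 0.95) -> tuple[float, float]:
    """DeLong-variance normal interval for a single AUC, clipped to [0, 1]."""
    preds._check_two_classes()
    auc, v10, v01 = _delong_components(preds.scores, preds.labels)

    def _component_var(v: np.ndarray) -> float:
        return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0

    var = _component_var(v10) / len(v10) + _component_var(v01) / len(v01)
    half = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(max(var, 0.0))
    return (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def binomial_ci(
    successes: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Binomial proportion CI; Wilson score by default, Clopper-Pearson via
    method="exact"."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    sm_method = {"wilson": "wilson", "exact": "beta"}[method]
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    return (float(lo), float(hi))


_METRIC_COUNTS = {
    "accuracy": lambda c: (c.tp + c.tn, c.total),
    "sensitivity": lambda c: (c.tp, c.tp + c.fn),
    "specificity": lambda c: (c.tn, c.tn + c.fp),
    "ppv": lambda c: (c.tp, c.tp + c.fp),
    "npv": lambda c: (c.tn, c.tn + c.fn),
}


def evaluate(
    preds: PredictionSet,
    threshold: float | None = None,
    tune_preds: PredictionSet | None = None,
    level: float = 0.95,
    ci_method: str = "wilson",
) -> EvaluationReport:
    """Full report: AUC + CI, thresholded confusion metrics + binomial CIs.

    The threshold is taken as given, or tuned by Youden's J on `tune_preds`
    (falling back to tuning on `preds` itself if neither is supplied).
    """
    if threshold is None:
        threshold = youden_threshold(tune_preds if tune_preds is not None else preds)
    counts = apply_threshold(preds, threshold)
    metrics = confusion_metrics(counts)
    cis: dict[str, tuple[float, float] | None] = {}
    for name, get in _METRIC_COUNTS.items():
        k, n = get(counts)
        cis[name] = binomial_ci(k, n, level, ci_method) if n > 0 else None
    cis["f1"] = None  # F1 is not a binomial proportion
    return EvaluationReport(
        auc=roc_auc(preds),
        auc_ci=auc_ci(preds, level),
        threshold=float(threshold),
        counts=counts,
        metrics=metrics,
        metric_cis=cis,
        provenance=preds.provenance,
    )


def subtype_reports(
    subtypes: dict[str, str],
    preds: PredictionSet,
    threshold: float | None = None,
    tune_preds: PredictionSet | None = None,
) -> dict[str, EvaluationReport | None]:
    """Evaluate the central and peripheral subsets.

    Each subset is all negative exams plus the positives of one subtype; a
    subset with no positives is reported as None (unavailable).
    """
    missing = [e for e in preds.exam_ids if e not in subtypes]
    if missing:
        raise ValueError(f"missing subtype annotation for {missing[:3]}...")
    neg_ids = {e for e, lab in zip(preds.exam_ids, preds.labels) if lab == 0}
    out: dict[str, EvaluationReport | None] = {}
    for subtype in ("central", "peripheral"):
        keep = neg_ids | {
            e
            for e, lab in zip(preds.exam_ids, preds.labels)
            if lab == 1 and subtypes[e] == subtype
        }
        sub = preds.subset(keep, provenance=f"{preds.provenance}:{subtype}")
        if sub.labels.sum() == 0:
            out[subtype] = None
            continue
        out[subtype] = evaluate(sub, threshold=threshold, tune_preds=tune_preds)
    return out
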