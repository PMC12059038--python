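"""Label-granularity sweep: train at each slice-label proportion, ensemble
the CV models, tune the operating threshold on a tuning split, and evaluate
on held-out and external splits — the full protocol behind the question
"how many slice labels does exam-level classification actually need?".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .evaluation import (
    EvaluationReport,
    PredictionSet,
    delong_test,
    ensemble_predictions,
    evaluate,
    roc_auc,
    subtype_reports,
    youden_threshold,
)
from .preprocess import ProcessedSequence, WindowSpec, preprocess_record
from .supervision import select_labeled_slices, validate_labels
from .synthetic import PhantomConfig, generate_cohort, shifted_config
from .training import TrainingConfig, predict_cohort, train_cv, train_fold

__all__ = [
    "SweepConfig",
    "SweepReport",
    "DEFAULT_PROPORTIONS",
    "split_cohort",
    "run_sweep",
    "compare_proportions",
    "label_granularity_trend",
]

DEFAULT_PROPORTIONS = (0.0, 0.025, 0.05, 0.10, 0.20, 0.275, 0.35, 0.425, 0.50, 0.75, 1.0)


@dataclass(frozen=True)
class SweepConfig:
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_seeds: int = 3

    def __post_init__(self):
        p = self.proportions
        if any(not (0.0 <= x <= 1.0) for x in p):
            raise ValueError("proportions must lie in [0, 1]")
        if list(p) != sorted(set(p)):
            raise ValueError("proportions must be sorted and unique")


def _tag(p: float) -> str:
    if p == 0.0:
        return "weak"
    if p == 1.0:
        return "strong"
    return "semi-weak"


@dataclass
class SweepReport:
    rows: list[dict]
    predictions: dict[float, dict[str, PredictionSet]]  # p -> split -> preds
    failures: dict[float, str]

    def row_for(self, p: float) -> dict:
        for row in self.rows:
            if row["proportion"] == p:
                return row
        raise KeyError(p)


def split_cohort(
    cohort: list, fractions: tuple[float, float, float], seed: int
) -> tuple[list, list, list]:
    """Stratified train/tuning/test split by exam label."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, tune, test = [], [], []
    items = list(cohort)
    for label in (0, 1):
        group = [r for r in items if r.exam_label == label]
        order = rng.permutation(len(group))
        n_train = int(round(fractions[0] * len(group)))
        n_tune = int(round(fractions[1] * len(group)))
        for rank, idx in enumerate(order):
            if rank < n_train:
                train.append(group[idx])
            elif rank < n_train + n_tune:
                tune.append(group[idx])
            else:
                test.append(group[idx])
    return train, tune, test


def run_sweep(
    train_set: list[ProcessedSequence],
    tune_set: list[ProcessedSequence],
    test_set: list[ProcessedSequence],
    sweep: SweepConfig,
    external_set: list[ProcessedSequence] | None = None,
    out_dir: str | Path | None = None,
) -> SweepReport:
    """Train CV models per proportion and report thresholds + metrics.

    A failing proportion is recorded in `failures` and skipped, not fatal.
    """
    subtypes = {s.exam_id: s.subtype for s in test_set}
    rows, predictions, failures = [], {}, {}
    for p in sweep.proportions:
        config = replace(sweep.training, proportion=p)
        try:
            results = train_cv(train_set, config)
            models = [m for m, _, _ in results]
            tune_preds = ensemble_predictions(
                [predict_cohort(m, tune_set) for m in models]
            )
            test_preds = ensemble_predictions(
                [predict_cohort(m, test_set) for m in models]
            )
            threshold = youden_threshold(tune_preds)
            report = evaluate(test_preds, threshold=threshold)
            sub_reports = subtype_reports(subtypes, test_preds, threshold=threshold)
            row = {
                "proportion": p,
                "tag": _tag(p),
                "labeled_slices_per_exam": int(
                    len(select_labeled_slices(train_set[0].depth, p))
                ),
                "threshold": threshold,
                "test": report,
                "central": sub_reports["central"],
                "peripheral": sub_reports["peripheral"],
            }
            predictions[p] = {"tune": tune_preds, "test": test_preds}
            if external_set is not None:
                ext_preds = ensemble_predictions(
                    [predict_cohort(m, external_set) for m in models]
                )
                row["external"] = evaluate(ext_preds, threshold=threshold)
                predictions[p]["external"] = ext_preds
            rows.append(row)
        except (ValueError, FloatingPointError, RuntimeError) as exc:
            failures[p] = f"{type(exc).__name__}: {exc}"
    report = SweepReport(rows=rows, predictions=predictions, failures=failures)
    if out_dir is not None:
        _persist(report, Path(out_dir))
    return report


def _persist(report: SweepReport, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = []
    for row in report.rows:
        entry = {
            k: v
            for k, v in row.items()
            if k in ("proportion", "tag", "labeled_slices_per_exam", "threshold")
        }
        for split in ("test", "central", "peripheral", "external"):
            rep = row.get(split)
            if isinstance(rep, EvaluationReport):
                entry[split] = {
                    "auc": rep.auc,
                    "auc_ci": rep.auc_ci,
                    "metrics": rep.metrics,
                    "counts": vars(rep.counts),
                }
        serializable.append(entry)
    with open(out_dir / "report.json", "w") as fh:
        json.dump({"rows": serializable, "failures": report.failures}, fh, indent=2)
    import pandas as pd

    frames = []
    for p, splits in report.predictions.items():
        for split, preds in splits.items():
            frames.append(
                pd.DataFrame(
                    {
                        "proportion": p,
                        "split": split,
                        "exam_id": preds.exam_ids,
                        "label": preds.labels,
                        "score": preds.scores,
                    }
                )
            )
    if frames:
        pd.concat(frames).to_csv(out_dir / "predictions.csv", index=False)


def compare_proportions(
    report: SweepReport, p_a: float, p_b: float, split: str = "test"
) -> dict:
    """Paired DeLong comparison between two proportions on a stored split."""
    try:
        preds_a = report.predictions[p_a][split]
        preds_b = report.predictions[p_b][split]
    except KeyError as exc:
        raise ValueError(f"missing stored predictions: {exc}") from exc
    auc_a, auc_b, z, p_value = delong_test(preds_a, preds_b)
    from .evaluation import auc_ci

    ci_a, ci_b = auc_ci(preds_a), auc_ci(preds_b)
    sentence = (
        f"AUC was {auc_a:.3f} ({ci_a[0]:.3f}, {ci_a[1]:.3f}) with "
        f"{100 * p_a:g}% of slice-level labels compared to {auc_b:.3f} "
        f"({ci_b[0]:.3f}, {ci_b[1]:.3f}) with {100 * p_b:g}% "
        f"(p = {p_value:.3f})"
    )
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "auc_ci_a": ci_a,
        "auc_ci_b": ci_b,
        "z": z,
        "p_value": p_value,
        "sentence": sentence,
    }


def label_granularity_trend(
    proportions: tuple[float, ...] = (0.0, 0.25, 1.0),
    seeds: tuple[int, ...] = (0, 1, 2),
    phantom: PhantomConfig | None = None,
    training: TrainingConfig | None = None,
    target_shape: tuple[int, int, int] = (16, 48, 48),
) -> dict[float, list[float]]:
    """Seed-averaged test AUC per proportion on a fresh phantom cohort.

    This is the desk-scale version of the label-granularity experiment: one
    model per (seed, proportion) on a single stratified train/val/test
    split, small peripheral-lesion phantoms by default. Returns
    {proportion: [auc per seed]}.
    """
    if phantom is None:
        phantom = PhantomConfig(n_exams=60, central_fraction=0.0)
    if training is None:
        training = trend_training_config()
    out: dict[float, list[float]] = {p: [] for p in proportions}
    for seed in seeds:
        cohort = generate_cohort(replace(phantom, seed=phantom.seed + seed))
        cohort, _ = validate_labels(cohort)
        processed = [
            preprocess_record(r, WindowSpec(), target_shape) for r in cohort
        ]
        train_set, val_set, test_set = split_cohort(processed, (0.5, 0.2, 0.3), seed)
        for p in proportions:
            config = replace(training, proportion=p, seed=training.seed + seed)
            model, _ = train_fold(train_set, val_set, config)
            preds = predict_cohort(model, test_set)
            out[p].append(roc_auc(preds))
    return out


def trend_training_config(seed: int = 0) -> TrainingConfig:
    """Desk-scale training settings used by the trend experiment."""
    from .model import ModelConfig
    from .preprocess import AugmentConfig

    return TrainingConfig(
        epochs_max=60,
        early_stop_patience=60,
        batch_size=8,
        t_max=60,
        lr_init=2e-3,
        lr_min=1e-5,
        seed=seed,
        model=ModelConfig(
            feature_dim=32,
            conv_channels=(8, 16, 32),
            rnn_hidden=32,
            rnn_layers=3,
            attention_dim=32,
        ),
        augment=AugmentConfig(flip_prob=0.5, noise_prob=1.0, noise_var=0.004),
        grad_clip=1.0,
    )
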