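"""Fold construction, LR schedule, weighted sampling, and the training loop.

Training smoke tests use the cheap mean-features backbone and very small
synthetic sequences so the whole file stays fast.
"""

import numpy as np
import pytest

from slicemil.model import ModelConfig
from slicemil.preprocess import ProcessedSequence
from slicemil.supervision import class_weights
from slicemil.training import (
    TrainingConfig,
    cosine_lr,
    make_folds,
    predict_cohort,
    train_cv,
    train_fold,
    weighted_sampler,
)

FAST_MODEL = ModelConfig(
    backbone="mean_features", feature_dim=8, rnn_hidden=6, rnn_layers=3,
    attention_dim=4,
)


def _toy_cohort(rng, n=12, depth=6, size=6):
    """Separable toy: positive exams contain bright slices."""
    cohort = []
    for i in range(n):
        label = i % 2
        frames = rng.random((depth, 3, size, size)) * 0.2
        slices = np.zeros(depth, dtype=np.int8)
        if label:
            k = int(rng.integers(1, depth - 1))
            frames[k] += 0.6
            slices[k] = 1
        cohort.append(
            ProcessedSequence(
                exam_id=f"e{i:02d}",
                frames=frames.astype(np.float32),
                slice_labels=slices,
                source_depth=depth,
                exam_label=label,
            )
        )
    return cohort


def _fast_config(**kw):
    defaults = dict(
        epochs_max=6,
        lr_init=5e-3,
        lr_min=1e-5,
        t_max=6,
        batch_size=4,
        early_stop_patience=6,
        k_folds=2,
        seed=3,
        model=FAST_MODEL,
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestFolds:
    def test_stratified_counts(self, rng):
        cohort = _toy_cohort(rng, n=10)
        folds = make_folds(cohort, 5, seed=0)
        for fold in range(5):
            ids = folds.val_ids(fold)
            labels = [next(s for s in cohort if s.exam_id == e).exam_label for e in ids]
            assert sorted(labels) == [0, 1]

    def test_partition_is_disjoint_and_complete(self, rng):
        cohort = _toy_cohort(rng, n=12)
        folds = make_folds(cohort, 3, seed=1)
        all_ids = sorted(folds.assignments)
        assert all_ids == sorted(s.exam_id for s in cohort)
        sizes = [len(folds.val_ids(f)) for f in range(3)]
        assert max(sizes) - min(sizes) <= 1

    def test_seed_determinism(self, rng):
        cohort = _toy_cohort(rng, n=12)
        assert make_folds(cohort, 3, 5).assignments == make_folds(cohort, 3, 5).assignments
        assert make_folds(cohort, 3, 5).assignments != make_folds(cohort, 3, 6).assignments

    def test_k_larger_than_class_rejected(self, rng):
        cohort = _toy_cohort(rng, n=6)
        with pytest.raises(ValueError):
            make_folds(cohort, 4, 0)


class TestCosineLR:
    def test_endpoints(self):
        config = TrainingConfig()
        assert cosine_lr(0, config) == pytest.approx(1e-4)
        assert cosine_lr(30, config) == pytest.approx(1e-6)

    def test_midpoint_closed_form(self):
        assert cosine_lr(15, TrainingConfig()) == pytest.approx(5.05e-5)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(-1, TrainingConfig())


class TestWeightedSampler:
    def test_balanced_cohort_equal_weights_uniform(self, rng):
        cohort = _toy_cohort(rng, n=10)
        weights = class_weights(10, 5, 5)
        ids = weighted_sampler(cohort, weights, np.random.default_rng(0), n_draws=5000)
        counts = {e: ids.count(e) for e in {s.exam_id for s in cohort}}
        assert max(counts.values()) < 2 * min(counts.values())

    def test_imbalanced_cohort_balances_classes(self, rng):
        # 30% positive with inverse-prevalence weights -> ~50% positive draws
        cohort = []
        for i in range(30):
            label = 1 if i < 9 else 0
            cohort.append(
                ProcessedSequence(
                    exam_id=f"e{i}",
                    frames=np.zeros((2, 3, 2, 2), dtype=np.float32),
                    slice_labels=np.zeros(2, dtype=np.int8),
                    source_depth=2,
                    exam_label=label,
                )
            )
        weights = class_weights(30, 9, 21)
        ids = weighted_sampler(cohort, weights, np.random.default_rng(1), n_draws=10_000)
        labels = {s.exam_id: s.exam_label for s in cohort}
        pos_frac = np.mean([labels[e] for e in ids])
        assert pos_frac == pytest.approx(0.5, abs=0.02)

    def test_stream_determinism(self, rng):
        cohort = _toy_cohort(rng, n=8)
        weights = class_weights(8, 4, 4)
        a = weighted_sampler(cohort, weights, np.random.default_rng(9))
        b = weighted_sampler(cohort, weights, np.random.default_rng(9))
        assert a == b


class TestTrainFold:
    def test_learns_separable_toy_cohort(self, rng):
        cohort = _toy_cohort(rng, n=16)
        model, history = train_fold(cohort[:12], cohort[12:], _fast_config(proportion=1.0))
        assert history[-1]["val_auc"] >= 0.75 or max(h["val_auc"] for h in history) >= 0.75

    def test_history_lr_matches_schedule(self, rng):
        cohort = _toy_cohort(rng)
        config = _fast_config(epochs_max=3)
        _, history = train_fold(cohort[:8], cohort[8:], config)
        for h in history:
            assert h["lr"] == pytest.approx(cosine_lr(h["epoch"], config))

    def test_identical_seeds_identical_trajectories(self, rng):
        cohort = _toy_cohort(rng)
        config = _fast_config(epochs_max=3)
        _, h1 = train_fold(cohort[:8], cohort[8:], config)
        _, h2 = train_fold(cohort[:8], cohort[8:], config)
        assert [h["train_loss"] for h in h1] == [h["train_loss"] for h in h2]

    def test_early_stop_returns_best_checkpoint(self, rng):
        cohort = _toy_cohort(rng)
        config = _fast_config(epochs_max=6, early_stop_patience=2)
        model, history = train_fold(cohort[:8], cohort[8:], config)
        best = max(h["val_auc"] for h in history)
        from slicemil.evaluation import roc_auc

        final_auc = roc_auc(predict_cohort(model, cohort[8:]))
        assert final_auc == pytest.approx(best, abs=1e-9)

    def test_weak_supervision_leaves_slice_head_untouched(self, rng):
        """At p=0 the slice head receives exactly zero gradient, so its
        parameters never move."""
        cohort = _toy_cohort(rng)
        config = _fast_config(proportion=0.0, epochs_max=2)
        from slicemil.model import build_model

        init_model = build_model(config.model, np.random.default_rng([config.seed, 0]))
        w0 = init_model.slice_head.weight.data.copy()
        model, _ = train_fold(cohort[:8], cohort[8:], config)
        np.testing.assert_array_equal(model.slice_head.weight.data, w0)


class TestTrainCV:
    def test_cv_covers_every_exam_exactly_once(self, rng):
        cohort = _toy_cohort(rng, n=12)
        config = _fast_config(epochs_max=2, k_folds=3)
        results = train_cv(cohort, config)
        assert len(results) == 3
        from slicemil.training import make_folds

        folds = make_folds(cohort, 3, config.seed)
        seen = []
        for _, _, fold in results:
            seen.extend(folds.val_ids(fold))
        assert sorted(seen) == sorted(s.exam_id for s in cohort)
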