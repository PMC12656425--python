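"""Scheduler, splits, augmentation, training loop, metrics, ablation."""

import numpy as np
import pandas as pd
import pytest

from voxfuse.errors import EmptyInputError, ValidationError
from voxfuse.fusion import ClassifierConfig
from voxfuse.synth import ClassProfile, CohortSpec, generate_cohort
from voxfuse.training import (
    LabeledDataset,
    SplitPlan,
    TrainingConfig,
    augment_features,
    cosine_lr,
    cross_validate,
    evaluate,
    metrics_from_confusion,
    report_from_scores,
    run_ablation,
    stratified_split,
    subject_wise_split,
    train,
)

#: desk-scale optimisation: same optimizer family and schedule shape as the
#: full-scale recipe, higher rate / fewer epochs for the small numpy model
FAST = dict(eta_max=1e-3, eta_min=1e-5, epochs=40)


class TestCosineSchedule:
    CFG = TrainingConfig()

    def test_starts_at_eta_max(self):
        assert cosine_lr(0, self.CFG) == pytest.approx(1e-4, rel=1e-12)

    def test_ends_at_eta_min(self):
        assert cosine_lr(self.CFG.epochs, self.CFG) == pytest.approx(1e-6, rel=1e-12)

    def test_midpoint_is_arithmetic_mean(self):
        assert cosine_lr(self.CFG.epochs // 2, self.CFG) == pytest.approx(
            (1e-4 + 1e-6) / 2, rel=1e-12
        )

    def test_monotone_non_increasing_and_bounded(self):
        lrs = [cosine_lr(t, self.CFG) for t in range(self.CFG.epochs + 1)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(1e-6 <= lr <= 1e-4 for lr in lrs)

    def test_epoch_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            cosine_lr(-1, self.CFG)
        with pytest.raises(ValidationError):
            cosine_lr(self.CFG.epochs + 1, self.CFG)


class TestSubjectWiseSplit:
    def test_sample_counts_near_targets(self, separable_dataset):
        plan = subject_wise_split(separable_dataset, (0.7, 0.15, 0.15), seed=0)
        n = len(separable_dataset)
        per_subject = 5
        assert abs(plan.train.size - 0.7 * n) <= per_subject
        assert abs(plan.val.size - 0.15 * n) <= per_subject
        assert abs(plan.test.size - 0.15 * n) <= per_subject

    def test_subject_sets_disjoint(self, separable_dataset):
        plan = subject_wise_split(separable_dataset, seed=1)
        plan.assert_no_subject_leakage(separable_dataset.subject_ids)

    def test_same_seed_reproduces_plan(self, separable_dataset):
        a = subject_wise_split(separable_dataset, seed=3)
        b = subject_wise_split(separable_dataset, seed=3)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_exhaustive_partition(self, separable_dataset):
        plan = subject_wise_split(separable_dataset, seed=4)
        combined = np.sort(np.concatenate([plan.train, plan.val, plan.test]))
        np.testing.assert_array_equal(combined, np.arange(len(separable_dataset)))

    def test_too_few_subjects_rejected(self):
        data = LabeledDataset(
            y=np.array([0, 1]), subject_ids=np.array(["a", "b"]),
            sample_ids=np.array(["s0", "s1"]), X_bio=np.zeros((2, 3)),
        )
        with pytest.raises(ValidationError):
            subject_wise_split(data, seed=0)

    def test_stratified_mode_keeps_class_balance(self, separable_dataset):
        plan = stratified_split(separable_dataset, 0.8, seed=0)
        y = separable_dataset.y
        overall = y.mean()
        assert abs(y[plan.train].mean() - overall) < 0.05
        assert plan.test.size == 0


class TestFeatureAugmentation:
    CFG = TrainingConfig()

    def test_zero_fraction_is_identity(self):
        m = np.random.default_rng(0).normal(size=(10, 3))
        cfg = TrainingConfig(feature_noise_frac=0.0)
        np.testing.assert_array_equal(
            augment_features(m, cfg, np.random.default_rng(0)), m
        )

    def test_constant_column_unchanged(self):
        m = np.column_stack([np.full(20, 3.0), np.arange(20.0)])
        out = augment_features(m, self.CFG, np.random.default_rng(0))
        np.testing.assert_array_equal(out[:, 0], m[:, 0])

    def test_noise_sd_matches_five_percent_of_range(self):
        rng = np.random.default_rng(0)
        m = np.tile(np.linspace(0.0, 10.0, 100), (100, 1)).T  # range 10 per column
        noise = augment_features(m, self.CFG, rng) - m
        assert abs(noise.std() - 0.5) / 0.5 < 0.1

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            augment_features(np.ones((1, 3)), self.CFG, np.random.default_rng(0))


class TestTrainingLoop:
    def test_separable_cohort_reaches_high_held_out_accuracy(
        self, separable_dataset, small_clf_cfg
    ):
        plan = subject_wise_split(separable_dataset, seed=0)
        cfg = TrainingConfig(seed=0, **FAST)
        fitted = train(separable_dataset, plan, cfg, model_cfg=small_clf_cfg)
        report = evaluate(fitted, separable_dataset, plan)
        assert report.accuracy >= 0.95

    def test_fixed_seed_gives_bit_identical_history(
        self, separable_dataset, small_clf_cfg
    ):
        plan = subject_wise_split(separable_dataset, seed=0)
        cfg = TrainingConfig(seed=7, epochs=5, **{k: v for k, v in FAST.items()
                                                  if k != "epochs"})
        h1 = train(separable_dataset, plan, cfg, model_cfg=small_clf_cfg).history
        h2 = train(separable_dataset, plan, cfg, model_cfg=small_clf_cfg).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_early_stopping_keeps_best_validation_checkpoint(
        self, separable_dataset, small_clf_cfg
    ):
        plan = subject_wise_split(separable_dataset, seed=0)
        cfg = TrainingConfig(seed=0, **FAST)
        fitted = train(separable_dataset, plan, cfg, model_cfg=small_clf_cfg)
        from voxfuse.fusion import cross_entropy

        val = separable_dataset
        idx = plan.val
        proba = fitted.model.predict_proba(fitted.features(val)[idx])
        final_val_loss = cross_entropy(proba, val.y[idx])
        assert final_val_loss <= fitted.history["val_loss"].min() + 1e-6

    def test_empty_split_rejected(self, separable_dataset, small_clf_cfg):
        plan = SplitPlan(train=np.array([], dtype=int),
                         val=np.arange(10), test=np.arange(10, 20),
                         fractions=(0.0, 0.5, 0.5), seed=0)
        with pytest.raises(EmptyInputError):
            train(separable_dataset, plan, TrainingConfig(), model_cfg=small_clf_cfg)


class TestEvaluation:
    def test_perfect_predictor_scores_one_everywhere(self):
        y = np.array([0, 1] * 10)
        proba = np.eye(2)[y] * 0.98 + 0.01
        r = report_from_scores(y, proba)
        assert r.accuracy == r.f1 == r.auc == r.specificity == 1.0

    def test_metrics_recomputable_from_confusion_matrix(self):
        confusion = np.array([[95, 5], [4, 96]])  # TN FP / FN TP
        m = metrics_from_confusion(confusion)
        assert m["accuracy"] == pytest.approx(191 / 200)
        assert m["precision"] == pytest.approx(96 / 101)
        assert m["recall"] == pytest.approx(96 / 100)
        assert m["specificity"] == pytest.approx(95 / 100)

    def test_constant_predictor_has_auc_half(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        proba = np.full((6, 2), 0.5)
        assert report_from_scores(y, proba).auc == pytest.approx(0.5)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValidationError):
            report_from_scores(np.zeros(5, dtype=int), np.full((5, 2), 0.5))

    def test_reported_metrics_match_confusion_matrix(self, separable_dataset,
                                                     small_clf_cfg):
        plan = subject_wise_split(separable_dataset, seed=0)
        cfg = TrainingConfig(seed=0, epochs=10, eta_max=1e-3, eta_min=1e-5)
        fitted = train(separable_dataset, plan, cfg, model_cfg=small_clf_cfg)
        r = evaluate(fitted, separable_dataset, plan)
        m = metrics_from_confusion(r.confusion)
        for key, value in m.items():
            assert getattr(r, key) == pytest.approx(value)


class TestCrossValidation:
    def test_fold_structure_and_coverage(self, separable_dataset, small_clf_cfg):
        cfg = TrainingConfig(seed=0, epochs=30, eta_max=1e-3, eta_min=1e-5)
        reports, summary = cross_validate(
            separable_dataset, k=3, cfg=cfg, model_cfg=small_clf_cfg
        )
        assert len(reports) == 3
        total = sum(r.y_true.size for r in reports)
        assert total == len(separable_dataset)  # each sample tested once
        assert summary["mean_accuracy"] >= 0.9

    def test_k_exceeding_subject_count_rejected(self, small_clf_cfg):
        data = LabeledDataset(
            y=np.array([0, 1, 0]), subject_ids=np.array(["a", "b", "c"]),
            sample_ids=np.array(["s0", "s1", "s2"]), X_bio=np.zeros((3, 2)),
        )
        with pytest.raises(ValidationError):
            cross_validate(data, k=5, cfg=TrainingConfig())


class TestAblation:
    def test_unknown_configuration_rejected(self, separable_dataset):
        with pytest.raises(ValidationError):
            run_ablation(separable_dataset, ["no_such_config"], TrainingConfig())

    def test_dropping_both_modalities_rejected(self, separable_dataset):
        with pytest.raises(ValidationError):
            run_ablation(
                separable_dataset, ["drop_biomarkers+drop_embeddings"],
                TrainingConfig(),
            )

    def test_grid_rows_share_one_split(self, separable_dataset, small_clf_cfg):
        cfg = TrainingConfig(seed=0, epochs=6, eta_max=1e-3, eta_min=1e-5)
        grid = ["full", "drop_embeddings", "no_batch_norm", "no_dropout",
                "late_fusion_voting", "logistic_baseline"]
        table = run_ablation(separable_dataset, grid, cfg,
                             model_cfg=small_clf_cfg)
        assert len(table) == 6
        assert table["split_hash"].nunique() == 1
        assert set(table["config"]) == set(grid)
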