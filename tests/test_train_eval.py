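"""Training protocol, folds, metrics and timing."""

import numpy as np
import pytest

from ecgfusion.ecg_io import EcgRecord, ValidationError
from ecgfusion.models import ModelConfig, build_model
from ecgfusion.train import (
    LABEL_TO_INT,
    ArrayDataset,
    TrainConfig,
    augment,
    compute_metrics,
    crossval,
    evaluate,
    make_folds,
    per_sample_time,
    train_two_stage,
)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

class TestAugment:
    def test_zero_parameters_is_identity(self, rng):
        rec = EcgRecord(rng.normal(size=500), record_id="r")
        out = augment(rec, warp_strength=0.0, jitter_sd=0.0, seed=3)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_length_preserved_and_deterministic(self, rng):
        rec = EcgRecord(rng.normal(size=777), record_id="r")
        a = augment(rec, warp_strength=0.03, seed=5)
        b = augment(rec, warp_strength=0.03, seed=5)
        c = augment(rec, warp_strength=0.03, seed=6)
        assert len(a) == 777
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_default_jitter_scales_with_peak(self, rng):
        x = rng.normal(size=2000)
        rec_small = EcgRecord(0.1 * x, record_id="s")
        rec_big = EcgRecord(10 * x, record_id="b")
        d_small = augment(rec_small, warp_strength=0, seed=1).samples - 0.1 * x
        d_big = augment(rec_big, warp_strength=0, seed=1).samples - 10 * x
        assert d_big.std() / d_small.std() == pytest.approx(100, rel=0.05)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

class TestMakeFolds:
    def test_exact_stratification_when_divisible(self):
        labels = np.array(["N"] * 60 + ["A"] * 20 + ["O"] * 15 + ["~"] * 5)
        plan = make_folds(labels, scheme="stratified_kfold", k=5, seed=0)
        for _, test in plan.folds:
            fold_labels = labels[test]
            assert (fold_labels == "N").sum() == 12
            assert (fold_labels == "A").sum() == 4
            assert (fold_labels == "O").sum() == 3
            assert (fold_labels == "~").sum() == 1

    def test_test_sets_partition_indices(self):
        labels = np.array(["N", "A", "O", "~"] * 10)
        plan = make_folds(labels, scheme="stratified_kfold", k=5, seed=1)
        all_test = np.concatenate([t for _, t in plan.folds])
        assert sorted(all_test) == list(range(40))
        for train, test in plan.folds:
            assert np.intersect1d(train, test).size == 0

    def test_deterministic_given_seed(self):
        labels = np.array(["N", "A", "O", "~"] * 10)
        a = make_folds(labels, scheme="stratified_kfold", k=5, seed=3)
        b = make_folds(labels, scheme="stratified_kfold", k=5, seed=3)
        for (ta, sa), (tb, sb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_sparse_class_rejected_by_name(self):
        labels = np.array(["N"] * 20 + ["~"] * 3)
        with pytest.raises(ValidationError, match="~"):
            make_folds(labels, scheme="stratified_kfold", k=5)

    def test_loso_one_fold_per_subject(self):
        labels = np.array(["N", "A"] * 7)
        subjects = np.repeat([f"s{i}" for i in range(7)], 2)
        plan = make_folds(labels, subjects, scheme="loso")
        assert len(plan.folds) == 7
        for train, test in plan.folds:
            test_subjects = set(subjects[test])
            assert len(test_subjects) == 1
            assert test_subjects.isdisjoint(set(subjects[train]))
        all_test = np.concatenate([t for _, t in plan.folds])
        assert sorted(all_test) == list(range(14))


# ---------------------------------------------------------------------------
# Two-stage protocol
# ---------------------------------------------------------------------------

def _toy_fusion_data(rng, n=32):
    y = np.tile(np.arange(4), n // 4)
    hc = (np.eye(4)[y] * 2 + rng.normal(0, 0.1, (n, 4))).astype(np.float32)
    images = rng.random((n, 32, 32, 3)).astype(np.float32)
    return ArrayDataset(images, hc, y)


class TestTwoStageProtocol:
    def test_stage1_backbone_bit_identical(self, rng):
        data = _toy_fusion_data(rng)
        model = build_model(ModelConfig(arch="simple_cnn", fusion=True,
                                        handcrafted_dim=4,
                                        image_size=(32, 32, 3), seed=4))
        before = {k: v.copy() for k, v in model.backbone.state_dict().items()}
        cfg = TrainConfig(stage1_epochs=5, stage2_epochs=0, batch_size=8, seed=1)
        history = train_two_stage(model, data, data, cfg)
        after = model.backbone.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        assert len(history["stage1"]["train_loss"]) == 5

    def test_stage2_updates_backbone(self, rng):
        data = _toy_fusion_data(rng)
        model = build_model(ModelConfig(arch="simple_cnn", fusion=True,
                                        handcrafted_dim=4,
                                        image_size=(32, 32, 3), seed=4))
        checksum0 = model.backbone_checksum()
        cfg = TrainConfig(stage1_epochs=1, stage2_epochs=1, batch_size=8, seed=1)
        train_two_stage(model, data, None, cfg)
        assert model.backbone_checksum() != checksum0

    def test_early_stopping_at_patience_boundary(self, rng):
        """With a vanishing learning rate the validation loss never improves
        after the first epoch, so training halts after patience more epochs."""
        data = _toy_fusion_data(rng)
        model = build_model(ModelConfig(arch="simple_cnn", fusion=True,
                                        handcrafted_dim=4,
                                        image_size=(32, 32, 3), seed=4))
        cfg = TrainConfig(stage1_epochs=50, stage2_epochs=0, batch_size=8,
                          stage1_head_lr=1e-20, early_stop_patience=3, seed=1)
        history = train_two_stage(model, data, data, cfg)
        assert len(history["stage1"]["val_loss"]) == 1 + 3

    def test_convergence_on_separable_data(self, rng):
        """Linearly separable handcrafted features are fit within stage 1
        (a linear-classifier oracle confirms separability first)."""
        from sklearn.linear_model import LogisticRegression

        data = _toy_fusion_data(rng, n=200)
        oracle = LogisticRegression(max_iter=1000).fit(data.handcrafted, data.labels)
        assert oracle.score(data.handcrafted, data.labels) == 1.0

        model = build_model(ModelConfig(arch="simple_cnn", fusion=True,
                                        handcrafted_dim=4,
                                        image_size=(32, 32, 3), seed=2))
        cfg = TrainConfig(stage1_epochs=10, stage2_epochs=0, seed=0)
        train_two_stage(model, data, None, cfg)
        model.eval()
        acc = (model.predict_proba(data.images, data.handcrafted).argmax(1)
               == data.labels).mean()
        assert acc >= 0.95

    def test_empty_training_set_rejected(self, rng):
        data = _toy_fusion_data(rng).subset(np.array([], dtype=int))
        model = build_model(ModelConfig(arch="simple_cnn", fusion=True,
                                        handcrafted_dim=4,
                                        image_size=(32, 32, 3), seed=0))
        with pytest.raises(ValidationError):
            train_two_stage(model, data, None, TrainConfig())


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def oracle_metrics(y_true, y_pred):
    """Brute-force accuracy / macro precision / macro F1 via per-class tallies,
    macro-averaged over classes present in y_true."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc = float(np.mean(y_true == y_pred))
    precs, f1s = [], []
    for c in sorted(set(y_true.tolist())):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        f1s.append(f1)
    return acc, float(np.mean(precs)), float(np.mean(f1s))


def oracle_auc(y_binary, scores):
    """Pairwise-comparison AUC: P(score+ > score-) with half-credit ties."""
    pos = scores[y_binary == 1]
    neg = scores[y_binary == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        scores = np.eye(4)[y]
        report = compute_metrics(y, y, scores)
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        assert all(v == 1.0 for v in report.per_class_auc.values())
        np.testing.assert_array_equal(report.confusion, np.eye(4))

    def test_hand_tallied_six_sample_case(self):
        y_true = np.array([LABEL_TO_INT[c] for c in "NNAAO~"])
        y_pred = np.array([LABEL_TO_INT[c] for c in "NAAAOO"])
        report = compute_metrics(y_true, y_pred)
        assert report.accuracy == pytest.approx(4 / 6)
        expected_confusion = np.array([
            [0.5, 0.5, 0.0, 0.0],   # N: one right, one called A
            [0.0, 1.0, 0.0, 0.0],   # A: both right
            [0.0, 0.0, 1.0, 0.0],   # O: right
            [0.0, 0.0, 1.0, 0.0],   # ~: called O
        ])
        np.testing.assert_array_equal(report.confusion, expected_confusion)
        assert np.allclose(report.confusion.sum(axis=1), 1.0)

    def test_matches_bruteforce_exhaustive_small_and_sampled_large(self):
        """All 4-class (y_true, y_pred) configurations at n<=3 exhaustively,
        plus seeded random configurations at n in 4..6."""
        from itertools import product

        cases = []
        for n in (1, 2, 3):
            for yt in product(range(4), repeat=n):
                for yp in product(range(4), repeat=n):
                    cases.append((np.array(yt), np.array(yp)))
        rng = np.random.default_rng(0)
        for n in (4, 5, 6):
            for _ in range(100):
                cases.append((rng.integers(0, 4, n), rng.integers(0, 4, n)))
        for y_true, y_pred in cases:
            report = compute_metrics(y_true, y_pred)
            acc, prec, f1 = oracle_metrics(y_true, y_pred)
            assert report.accuracy == pytest.approx(acc)
            assert report.macro_precision == pytest.approx(prec)
            assert report.macro_f1 == pytest.approx(f1)

    def test_auc_matches_pairwise_oracle(self, rng):
        y = rng.integers(0, 4, 200)
        scores = rng.random((200, 4))
        report = compute_metrics(y, scores.argmax(1), scores)
        for c, lab in enumerate("NAO~"):
            lab = {0: "N", 1: "A", 2: "O", 3: "~"}[c]
            expected = oracle_auc((y == c).astype(int), scores[:, c])
            assert report.per_class_auc[lab] == pytest.approx(expected, abs=1e-12)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(11)
        y = np.tile(np.arange(4), 2500)
        scores = rng.random((10_000, 4))
        report = compute_metrics(y, scores.argmax(1), scores)
        for v in report.per_class_auc.values():
            assert v == pytest.approx(0.5, abs=0.02)

    def test_single_class_test_set_flags_auc(self):
        y = np.zeros(5, dtype=int)
        scores = np.random.default_rng(0).random((5, 4))
        report = compute_metrics(y, scores.argmax(1), scores)
        assert all(np.isnan(v) for v in report.per_class_auc.values())


class TestTiming:
    def test_worked_example(self):
        t = per_sample_time(56.28, 8528)
        assert t.t_per_sample == pytest.approx(0.0066, abs=1e-4)

    @pytest.mark.parametrize("total,n,expected", [(1.0, 1, 1.0), (100.0, 50, 2.0)])
    def test_exact_quotient(self, total, n, expected):
        t = per_sample_time(total, n)
        assert t.t_per_sample == total / n == expected

    def test_zero_samples_rejected(self):
        with pytest.raises(ValidationError):
            per_sample_time(1.0, 0)


# ---------------------------------------------------------------------------
# Cross-validated pipeline and leakage guards
# ---------------------------------------------------------------------------

class TestCrossvalPipeline:
    def test_loso_test_subjects_absent_from_training(self, small_dataset):
        plan = make_folds(small_dataset.labels, small_dataset.subject_ids,
                          scheme="loso")
        for train, test in plan.folds:
            assert set(small_dataset.subject_ids[test]).isdisjoint(
                set(small_dataset.subject_ids[train]))

    def test_standardizer_and_reducer_fit_on_training_rows_only(
            self, small_dataset, monkeypatch):
        from ecgfusion import train as train_mod

        fit_sizes = []
        orig_fit = train_mod.Standardizer.fit

        def spy_fit(self, X):
            fit_sizes.append(X.shape[0])
            return orig_fit(self, X)

        monkeypatch.setattr(train_mod.Standardizer, "fit", spy_fit)
        cfg = TrainConfig(stage1_epochs=1, stage2_epochs=0, batch_size=8)
        result = crossval(small_dataset,
                          ModelConfig(arch="simple_cnn", fusion=True),
                          cfg, scheme="stratified_kfold", k=3,
                          fusion_strategy="pca", seed=0)
        n = len(small_dataset)
        for (train_idx, test_idx), n_fit in zip(result.plan.folds, fit_sizes):
            n_train = train_idx.size
            n_val = max(1, round(0.2 * n_train))
            assert n_fit == n_train - n_val       # train minus validation split
            assert n_fit < n                      # never the whole dataset

    def test_augmentation_provider_sees_training_indices_only(self, small_dataset):
        calls = []

        def provider(fit_idx, fold_i):
            calls.append((fold_i, np.array(fit_idx)))
            return None

        cfg = TrainConfig(stage1_epochs=1, stage2_epochs=0, batch_size=8)
        result = crossval(small_dataset,
                          ModelConfig(arch="simple_cnn", fusion=True),
                          cfg, scheme="stratified_kfold", k=3, seed=0,
                          extra_train_provider=provider)
        assert len(calls) == len(result.plan.folds)
        for (fold_i, fit_idx), (train_idx, test_idx) in zip(calls, result.plan.folds):
            assert np.isin(fit_idx, train_idx).all()
            assert not np.isin(fit_idx, test_idx).any()

    def test_record_level_crossval_with_augmentation(self, small_balanced_records):
        from ecgfusion.features import ScatteringConfig
        from ecgfusion.train import crossval_records

        cfg = ScatteringConfig(J=3, Q=2, T=512, n_frames=16, n_tail=0, j2_max=3)
        result = crossval_records(
            small_balanced_records,
            ModelConfig(arch="simple_cnn", fusion=True),
            TrainConfig(stage1_epochs=3, stage2_epochs=0, batch_size=8),
            scheme="stratified_kfold", k=3, augment_per_record=1,
            scattering_config=cfg, target_len=1024, seed=0)
        assert len(result.fold_reports) == 3
        for report in result.fold_reports:
            assert 0.0 <= report.accuracy <= 1.0
            assert report.per_sample_time_s is not None

    def test_evaluate_reports_latency(self, small_dataset):
        model = build_model(ModelConfig(arch="simple_cnn", fusion=False, seed=0))
        report = evaluate(model, ArrayDataset(small_dataset.images, None,
                                              small_dataset.labels))
        assert report.per_sample_time_s is not None
        assert report.per_sample_time_s > 0
        assert report.n_samples == len(small_dataset)
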