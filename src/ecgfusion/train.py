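"""Two-stage training protocol, cross-validation schemes, metrics, timing.

Training follows the staged recipe for fusion models: stage 1 freezes the
backbone and trains only the fusion head for up to 50 epochs (Adam, lr 1e-3,
weight decay 1e-5, batch 64); stage 2 fine-tunes backbone and head jointly
for up to 20 epochs with differential learning rates (backbone 1e-5, head
1e-3). Early stopping on validation loss (patience 20) applies within each
stage, and the best-validation-loss weights are restored. Non-fusion models
use the single-stage regime with the same optimizer settings.

Evaluation supports stratified k-fold (k=5) and leave-one-subject-out
cross-validation, reporting accuracy, macro F1, macro precision, one-vs-rest
per-class ROC-AUC, the row-normalized confusion matrix, and per-sample
inference latency t_total / N_samples.

Leakage guards are structural: feature standardization and PCA are fit on
training folds only, augmentation is applied to training records only, and
LOSO test subjects never appear in training indices.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from . import nn
from .ecg_io import LABELS, EcgRecord, RecordSet, ValidationError, preprocess
from .features import ScatteringConfig, extract_combined
from .models import EcgClassifier, ModelConfig, build_model
from .reduce import FusionReducer, record_vector
from .scalogram import ScalogramConfig, scalogram_image

LABEL_TO_INT = {lab: i for i, lab in enumerate(LABELS)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer and protocol settings (Adam, cross-entropy throughout)."""

    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 64
    early_stop_patience: int = 20
    stage1_epochs: int = 50
    stage1_head_lr: float = 1e-3
    stage2_epochs: int = 20
    stage2_backbone_lr: float = 1e-5
    stage2_head_lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lr", "stage1_head_lr", "stage2_backbone_lr", "stage2_head_lr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.early_stop_patience < 1:
            raise ValidationError("early_stop_patience must be >= 1")


@dataclass
class ArrayDataset:
    """Extracted tensors for a set of records."""

    images: np.ndarray                      # (n, 128, 128, 3)
    handcrafted: np.ndarray | None          # (n, d) or None
    labels: np.ndarray                      # (n,) ints
    subject_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return self.labels.size

    def subset(self, idx: np.ndarray) -> "ArrayDataset":
        return ArrayDataset(
            self.images[idx],
            None if self.handcrafted is None else self.handcrafted[idx],
            self.labels[idx],
            None if self.subject_ids is None else self.subject_ids[idx],
        )

    @staticmethod
    def concatenate(parts: list["ArrayDataset"]) -> "ArrayDataset":
        return ArrayDataset(
            np.concatenate([p.images for p in parts]),
            None if parts[0].handcrafted is None
            else np.concatenate([p.handcrafted for p in parts]),
            np.concatenate([p.labels for p in parts]),
            None if parts[0].subject_ids is None
            else np.concatenate([p.subject_ids for p in parts]),
        )


# ---------------------------------------------------------------------------
# Augmentation (training only; the pipeline never applies it to val/test)
# ---------------------------------------------------------------------------

def augment(
    record: EcgRecord,
    warp_strength: float = 0.03,
    jitter_sd: float | None = None,
    seed: int = 0,
) -> EcgRecord:
    """Time-warp + jitter augmentation of one record.

    Time warping remaps the time axis through a smooth monotone spline whose
    knot displacements are bounded by ``warp_strength`` (fraction of the
    record length), preserving length. Jitter adds white Gaussian noise;
    by default its SD is 2% of the peak absolute amplitude. Deterministic
    given the seed; zero strength and zero jitter is the identity.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(record.samples, dtype=np.float64)
    n = x.size
    out = x
    if warp_strength > 0 and n > 8:
        n_knots = 8
        knots = np.linspace(0, n - 1, n_knots)
        disp = rng.uniform(-warp_strength, warp_strength, size=n_knots) * n
        disp[0] = disp[-1] = 0.0
        warped_knots = np.clip(knots + disp, 0, n - 1)
        warped_knots = np.maximum.accumulate(warped_knots)  # monotone guard
        mapping = CubicSpline(knots, warped_knots)(np.arange(n))
        mapping = np.clip(np.maximum.accumulate(mapping), 0, n - 1)
        out = np.interp(mapping, np.arange(n), x)
    if jitter_sd is None:
        peak = float(np.max(np.abs(x))) if n else 0.0
        jitter = 0.02 * peak
    else:
        jitter = jitter_sd
    if jitter > 0:
        out = out + rng.normal(0.0, jitter, size=n)
    return replace(record, samples=out)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    k: int


def make_folds(
    labels,
    subject_ids=None,
    scheme: str = "stratified_kfold",
    k: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Build stratified k-fold or leave-one-subject-out splits.

    Stratified folds keep per-fold class proportions within one sample of
    the global proportions and are a deterministic function of
    (labels, k, seed). LOSO yields one fold per distinct subject with all of
    that subject's records in the test set only.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if scheme == "stratified_kfold":
        values, counts = np.unique(labels.astype(str), return_counts=True)
        for v, c in zip(values, counts):
            if c < k:
                raise ValidationError(
                    f"class {v!r} has only {c} samples; needs >= {k} for "
                    f"{k}-fold stratification"
                )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(n), labels.astype(str))]
        return FoldPlan("stratified_kfold", folds, k)
    if scheme == "loso":
        if subject_ids is None:
            raise ValidationError("loso requires subject_ids")
        subject_ids = np.asarray(subject_ids, dtype=object)
        subjects = sorted(set(subject_ids))
        folds = []
        idx = np.arange(n)
        for s in subjects:
            test = idx[subject_ids == s]
            train = idx[subject_ids != s]
            folds.append((train, test))
        return FoldPlan("loso", folds, len(subjects))
    raise ValidationError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Standardization (train-fold statistics only)
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.std = std
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValidationError("standardizer not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _dataset_loss(model: EcgClassifier, data: ArrayDataset, batch_size: int,
                  embeddings: np.ndarray | None = None) -> float:
    model.eval()
    total, count = 0.0, 0
    with nn.no_grad():
        for i in range(0, len(data), batch_size):
            sl = slice(i, i + batch_size)
            if embeddings is not None:
                emb = nn.Tensor(embeddings[sl])
                logits = model.head_logits(
                    emb, None if data.handcrafted is None else data.handcrafted[sl])
            else:
                logits = model.forward(
                    data.images[sl],
                    None if data.handcrafted is None else data.handcrafted[sl])
            batch_n = len(data.labels[sl])
            loss = nn.cross_entropy(logits, data.labels[sl])
            total += float(loss.data) * batch_n
            count += batch_n
    return total / max(count, 1)


def _precompute_embeddings(model: EcgClassifier, data: ArrayDataset,
                           batch_size: int) -> np.ndarray:
    """Frozen-backbone embeddings (eval mode, so deterministic)."""
    model.eval()
    outs = []
    with nn.no_grad():
        for i in range(0, len(data), batch_size):
            outs.append(model.embed(data.images[i:i + batch_size]).data)
    return np.concatenate(outs, axis=0)


def _run_stage(
    model: EcgClassifier,
    train_data: ArrayDataset,
    val_data: ArrayDataset | None,
    optimizer: nn.Adam,
    epochs: int,
    patience: int,
    batch_size: int,
    rng: np.random.Generator,
    train_embeddings: np.ndarray | None = None,
    val_embeddings: np.ndarray | None = None,
) -> dict:
    """One training stage with early stopping on validation loss."""
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    wait = 0
    for _ in range(epochs):
        model.train()
        epoch_loss, seen = 0.0, 0
        for idx in _batches(len(train_data), batch_size, rng):
            if train_embeddings is not None:
                emb = nn.Tensor(train_embeddings[idx])
                logits = model.head_logits(
                    emb,
                    None if train_data.handcrafted is None
                    else train_data.handcrafted[idx])
            else:
                logits = model.forward(
                    train_data.images[idx],
                    None if train_data.handcrafted is None
                    else train_data.handcrafted[idx])
            loss = nn.cross_entropy(logits, train_data.labels[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * idx.size
            seen += idx.size
        history["train_loss"].append(epoch_loss / max(seen, 1))
        if val_data is None:
            continue
        val_loss = _dataset_loss(model, val_data, batch_size, val_embeddings)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def train_two_stage(
    model: EcgClassifier,
    train_data: ArrayDataset,
    val_data: ArrayDataset | None,
    config: TrainConfig | None = None,
) -> dict:
    """Staged protocol for fusion models; single-stage for pure-image models.

    Stage 1 freezes the backbone (its parameters are bit-identical
    afterwards) and trains the head; stage 2 fine-tunes jointly with
    differential learning rates. Early stopping applies within each stage
    and the best-validation weights are restored per stage.
    """
    config = config or TrainConfig()
    if len(train_data) == 0:
        raise ValidationError("empty training set")
    rng = np.random.default_rng(config.seed)

    if not model.config.fusion:
        opt = nn.Adam([{"params": model.parameters(), "lr": config.lr}],
                      weight_decay=config.weight_decay)
        history = _run_stage(model, train_data, val_data, opt,
                             config.stage1_epochs, config.early_stop_patience,
                             config.batch_size, rng)
        return {"stage1": history}

    # Stage 1: frozen backbone -> embeddings are constant; cache them.
    model.freeze_backbone()
    checksum_before = model.backbone_checksum()
    train_emb = _precompute_embeddings(model, train_data, config.batch_size)
    val_emb = (None if val_data is None
               else _precompute_embeddings(model, val_data, config.batch_size))
    head_params = [p for p in model.head.parameters()]
    opt1 = nn.Adam([{"params": head_params, "lr": config.stage1_head_lr}],
                   weight_decay=config.weight_decay)
    hist1 = _run_stage(model, train_data, val_data, opt1,
                       config.stage1_epochs, config.early_stop_patience,
                       config.batch_size, rng,
                       train_embeddings=train_emb, val_embeddings=val_emb)
    assert model.backbone_checksum() == checksum_before

    # Stage 2: joint fine-tuning with differential learning rates.
    model.unfreeze_backbone()
    hist2: dict = {"train_loss": [], "val_loss": []}
    if config.stage2_epochs > 0:
        opt2 = nn.Adam(
            [
                {"params": model.backbone.parameters(), "lr": config.stage2_backbone_lr},
                {"params": head_params, "lr": config.stage2_head_lr},
            ],
            weight_decay=config.weight_decay,
        )
        hist2 = _run_stage(model, train_data, val_data, opt2,
                           config.stage2_epochs, config.early_stop_patience,
                           config.batch_size, rng)
    return {"stage1": hist1, "stage2": hist2}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: float
    macro_f1: float
    macro_precision: float
    per_class_auc: dict[str, float]         # NaN where the class is absent
    mean_auc: float
    confusion: np.ndarray                   # (4, 4), row-normalized
    per_sample_time_s: float | None = None
    n_samples: int = 0


@dataclass
class TimingReport:
    t_total: float
    n_samples: int
    t_per_sample: float


def per_sample_time(t_total: float, n_samples: int) -> TimingReport:
    """Normalized inference latency: t_total / N_samples."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if t_total < 0:
        raise ValidationError("t_total must be non-negative")
    return TimingReport(t_total, n_samples, t_total / n_samples)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    t_total: float | None = None,
) -> MetricsReport:
    """Accuracy, macro F1/precision, one-vs-rest AUC, normalized confusion.

    ``scores`` holds per-class probabilities (n, 4). Classes absent from
    ``y_true`` are marked not-applicable: NaN AUC, an all-zero confusion
    row, and exclusion from the macro F1/precision averages (so a fold whose
    test subject lacks a rhythm class is not penalized for it).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    all_cls = np.arange(len(LABELS))
    present_cls = np.unique(y_true)
    acc = accuracy_score(y_true, y_pred)
    f1 = f1_score(y_true, y_pred, labels=present_cls, average="macro", zero_division=0)
    prec = precision_score(y_true, y_pred, labels=present_cls, average="macro",
                           zero_division=0)
    aucs: dict[str, float] = {}
    for c, lab in enumerate(LABELS):
        mask = y_true == c
        if scores is None or mask.all() or not mask.any():
            aucs[lab] = float("nan")
        else:
            aucs[lab] = float(roc_auc_score(mask.astype(int), scores[:, c]))
    present = [v for v in aucs.values() if not np.isnan(v)]
    mean_auc = float(np.mean(present)) if present else float("nan")
    cm = confusion_matrix(y_true, y_pred, labels=all_cls).astype(np.float64)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, row_sums, out=np.zeros_like(cm), where=row_sums > 0)
    report = MetricsReport(float(acc), float(f1), float(prec), aucs, mean_auc, cm,
                           n_samples=y_true.size)
    if t_total is not None:
        report.per_sample_time_s = per_sample_time(t_total, y_true.size).t_per_sample
    return report


def evaluate(model: EcgClassifier, test_data: ArrayDataset,
             batch_size: int = 64) -> MetricsReport:
    """Predict on a held-out set and report the full metrics suite."""
    model.eval()
    probs = []
    t0 = time.perf_counter()
    for i in range(0, len(test_data), batch_size):
        sl = slice(i, i + batch_size)
        probs.append(model.predict_proba(
            test_data.images[sl],
            None if test_data.handcrafted is None else test_data.handcrafted[sl]))
    t_total = time.perf_counter() - t0
    scores = np.concatenate(probs, axis=0)
    y_pred = scores.argmax(axis=1)
    return compute_metrics(test_data.labels, y_pred, scores, t_total=t_total)


# ---------------------------------------------------------------------------
# Full cross-validated pipeline on RecordSets
# ---------------------------------------------------------------------------

def extract_dataset(
    records: RecordSet,
    scattering_config: ScatteringConfig | None = None,
    scalogram_config: ScalogramConfig | None = None,
    target_len: int = 8527,
    with_handcrafted: bool = True,
    dtype: type = np.float32,
) -> ArrayDataset:
    """Preprocess every record and extract images + handcrafted vectors."""
    scattering_config = scattering_config or ScatteringConfig(T=target_len)
    images, vectors, labels = [], [], []
    for rec in records:
        pre = preprocess(rec, target_len=target_len)
        images.append(scalogram_image(pre, scalogram_config).pixels.astype(np.float32))
        if with_handcrafted:
            combined = extract_combined(pre, scattering_config, dtype=dtype)
            vectors.append(record_vector(combined))
        labels.append(LABEL_TO_INT[rec.label])
    return ArrayDataset(
        np.stack(images),
        np.stack(vectors) if with_handcrafted else None,
        np.asarray(labels, dtype=np.int64),
        records.subject_ids,
    )


@dataclass
class CrossvalResult:
    fold_reports: list[MetricsReport]
    plan: FoldPlan

    @property
    def macro_f1(self) -> float:
        return float(np.mean([r.macro_f1 for r in self.fold_reports]))

    @property
    def accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports]))


def crossval(
    data: ArrayDataset,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    scheme: str = "stratified_kfold",
    k: int = 5,
    fusion_strategy: str = "concat",
    variance_target: float = 0.95,
    val_fraction: float = 0.2,
    seed: int = 0,
    extra_train_provider=None,
) -> CrossvalResult:
    """Cross-validated training/evaluation with structural leakage guards.

    Per fold: a validation split is carved out of the training fold (for
    early stopping), the handcrafted standardizer and the fusion reducer
    (PCA/weighting) are fit on training rows only, the model is trained with
    the staged protocol, and metrics are computed on the untouched test fold.

    ``extra_train_provider(fit_idx, fold_i)`` may return an
    :class:`ArrayDataset` of additional *training-only* samples (e.g.
    augmented copies); it is only ever called with training-fold indices, so
    augmentation can never leak into validation or test data.
    """
    train_config = train_config or TrainConfig(seed=seed)
    plan = make_folds(data.labels, data.subject_ids, scheme=scheme, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    reports = []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        assert np.intersect1d(train_idx, test_idx).size == 0
        perm = rng.permutation(train_idx.size)
        n_val = max(1, int(round(val_fraction * train_idx.size)))
        val_idx = train_idx[perm[:n_val]]
        fit_idx = train_idx[perm[n_val:]]

        fold_train = data.subset(fit_idx)
        if extra_train_provider is not None:
            extra = extra_train_provider(fit_idx, fold_i)
            if extra is not None and len(extra):
                fold_train = ArrayDataset.concatenate([fold_train, extra])
        fold_val = data.subset(val_idx)
        fold_test = data.subset(test_idx)

        if data.handcrafted is not None:
            std = Standardizer().fit(fold_train.handcrafted)
            reducer = FusionReducer(fusion_strategy, variance_target).fit(
                std.apply(fold_train.handcrafted))
            tx = lambda X: reducer.apply(std.apply(X)).astype(np.float32)  # noqa: E731
            fold_train.handcrafted = tx(fold_train.handcrafted)
            fold_val.handcrafted = tx(fold_val.handcrafted)
            fold_test.handcrafted = tx(fold_test.handcrafted)
            hdim = fold_train.handcrafted.shape[1]
        else:
            hdim = 0

        cfg = copy.deepcopy(model_config)
        cfg.handcrafted_dim = hdim
        cfg.seed = int(rng.integers(0, 2**31 - 1))
        model = build_model(cfg)
        fold_cfg = replace(train_config, seed=int(rng.integers(0, 2**31 - 1)))
        train_two_stage(model, fold_train, fold_val, fold_cfg)
        reports.append(evaluate(model, fold_test))
    return CrossvalResult(reports, plan)


def crossval_records(
    records: RecordSet,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    scheme: str = "stratified_kfold",
    k: int = 5,
    augment_per_record: int = 0,
    warp_strength: float = 0.03,
    jitter_sd: float | None = None,
    scattering_config: ScatteringConfig | None = None,
    scalogram_config: ScalogramConfig | None = None,
    target_len: int = 8527,
    fusion_strategy: str = "concat",
    variance_target: float = 0.95,
    seed: int = 0,
) -> CrossvalResult:
    """Record-level cross-validation with optional training-only augmentation.

    Augmented copies (time warp + jitter) are generated per fold from the
    training-fold records only, then pass through the same preprocessing and
    feature extraction as the originals.
    """
    base = extract_dataset(records, scattering_config, scalogram_config,
                           target_len=target_len,
                           with_handcrafted=model_config.fusion)

    provider = None
    if augment_per_record > 0:
        def provider(fit_idx, fold_i):
            aug_records = []
            for copy_i in range(augment_per_record):
                for ridx in fit_idx:
                    rec = records[int(ridx)]
                    aug = augment(rec, warp_strength, jitter_sd,
                                  seed=seed * 1_000_003 + fold_i * 1009
                                  + copy_i * 131 + int(ridx))
                    aug.record_id = f"{rec.record_id}-aug{fold_i}-{copy_i}"
                    aug_records.append(aug)
            return extract_dataset(
                RecordSet(aug_records), scattering_config, scalogram_config,
                target_len=target_len, with_handcrafted=model_config.fusion)

    return crossval(base, model_config, train_config, scheme=scheme, k=k,
                    fusion_strategy=fusion_strategy,
                    variance_target=variance_target, seed=seed,
                    extra_train_provider=provider)


def save_crossval_report(result: CrossvalResult, directory) -> None:
    """Write a JSON summary, a CSV metrics table and per-fold row-normalized
    confusion matrices (CSV) for a cross-validation run."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, r in enumerate(result.fold_reports):
        rows.append({
            "fold": i,
            "accuracy": r.accuracy,
            "macro_f1": r.macro_f1,
            "macro_precision": r.macro_precision,
            "mean_auc": r.mean_auc,
            "per_sample_time_s": r.per_sample_time_s,
            "n_samples": r.n_samples,
        })
        pd.DataFrame(r.confusion, index=list(LABELS),
                     columns=list(LABELS)).to_csv(
            directory / f"confusion_fold{i}.csv")
    pd.DataFrame(rows).to_csv(directory / "fold_metrics.csv", index=False)
    summary = {
        "scheme": result.plan.scheme,
        "k": result.plan.k,
        "accuracy": result.accuracy,
        "macro_f1": result.macro_f1,
    }
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))


def synthetic_recovery_benchmark(
    n: int = 200,
    n_subjects: int = 10,
    seeds: tuple[int, ...] = (0, 1, 2),
    arch: str = "simple_cnn",
    fusion_strategy: str = "concat",
    train_config: TrainConfig | None = None,
) -> dict:
    """End-to-end parameter-recovery study on synthetic data.

    For each seed: generate a balanced n-record synthetic dataset grouped
    into ``n_subjects`` subjects (classes differ in RR regularity, morphology
    and noise level, so the handcrafted features carry class information),
    run the full pipeline (preprocess, scattering + statistics, scalograms),
    and score a fusion model with leave-one-subject-out cross-validation.
    Returns per-seed macro F1 plus the seed average.

    The default training budget is scaled to this problem size (stage 1
    30 epochs on the frozen-backbone head, stage 2 joint fine-tuning for
    2 epochs).
    """
    from .synthetic import generate_dataset

    per_seed = []
    for seed in seeds:
        records = generate_dataset(n, imbalance="balanced", seed=seed,
                                   records_per_subject=max(1, n // n_subjects))
        data = extract_dataset(records)
        cfg = train_config or TrainConfig(stage1_epochs=30, stage2_epochs=2,
                                          seed=seed)
        result = crossval(data, ModelConfig(arch=arch, fusion=True),
                          cfg, scheme="loso",
                          fusion_strategy=fusion_strategy, seed=seed)
        per_seed.append({"seed": seed, "macro_f1": result.macro_f1,
                         "accuracy": result.accuracy})
    return {
        "per_seed": per_seed,
        "mean_macro_f1": float(np.mean([r["macro_f1"] for r in per_seed])),
        "mean_accuracy": float(np.mean([r["accuracy"] for r in per_seed])),
    }
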