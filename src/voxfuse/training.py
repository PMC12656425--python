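"""Training regimen, subject-wise splitting, metrics and the ablation grid.

Training uses Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8) with weight
decay, a cosine-annealed learning rate

    eta_t = eta_min + (eta_max - eta_min) (1 + cos(pi t / T)) / 2

from eta_max = 1e-4 at epoch 0 to eta_min = 1e-6 at epoch T = 100, and
early stopping on validation loss (patience 10); the checkpoint with the
lowest validation loss is kept.  Splits are subject-wise by default
(70/15/15): all recordings of one speaker land in a single subset, which
is the only split hygiene that prevents identity leakage in voice data.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from voxfuse.biomarkers import StandardizationStats, apply_standardization, fit_standardization
from voxfuse.errors import DependencyError, EmptyInputError, ValidationError
from voxfuse.fusion import (
    ClassifierConfig,
    HybridFusionClassifier,
    cross_entropy,
    cross_entropy_tensor,
)
from voxfuse._autodiff import Tensor
from voxfuse.nn import Adam
from voxfuse.synth import Cohort


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer, schedule and regularisation settings."""

    eta_max: float = 1e-4
    eta_min: float = 1e-6
    epochs: int = 100                # T
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    eps_adam: float = 1e-8
    weight_decay: float = 1e-4
    patience: int = 10               # early-stopping epochs
    min_delta: float = 1e-5          # improvement threshold on val loss
    feature_noise_frac: float = 0.05  # train-time biomarker augmentation
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.eta_min <= self.eta_max):
            raise ValidationError("need 0 < eta_min <= eta_max")
        if self.epochs < 1 or self.patience < 1:
            raise ValidationError("epochs and patience must be >= 1")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValidationError("beta1, beta2 must be in (0, 1)")


def cosine_lr(t: int, cfg: TrainingConfig) -> float:
    """eta_t = eta_min + (eta_max - eta_min)(1 + cos(pi t / T)) / 2."""
    if not (0 <= t <= cfg.epochs):
        raise ValidationError(f"epoch {t} outside [0, {cfg.epochs}]")
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (
        1.0 + math.cos(math.pi * t / cfg.epochs)
    )


# --------------------------------------------------------------------------
# dataset and splits

@dataclass
class LabeledDataset:
    """Per-sample biomarkers and/or embeddings with binary labels.

    Every sample carries a subject id; labels are 0 (Healthy) / 1 (PD).
    """

    y: np.ndarray
    subject_ids: np.ndarray
    sample_ids: np.ndarray
    X_bio: Optional[np.ndarray] = None
    X_emb: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        if self.X_bio is None and self.X_emb is None:
            raise ValidationError("dataset needs at least one feature block")
        n = self.y.size
        for block in (self.X_bio, self.X_emb):
            if block is not None and block.shape[0] != n:
                raise ValidationError("feature block row count != label count")
        if len(self.subject_ids) != n:
            raise ValidationError("every sample needs a subject_id")

    def __len__(self) -> int:
        return self.y.size

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "LabeledDataset":
        t = cohort.table
        return cls(
            y=t["label"].to_numpy(),
            subject_ids=t["subject_id"].to_numpy(),
            sample_ids=t["sample_id"].to_numpy(),
            X_bio=t[cohort.feature_cols].to_numpy(dtype=np.float64),
            X_emb=t[cohort.embedding_cols].to_numpy(dtype=np.float64),
        )

    def permuted_labels(self, seed: int) -> "LabeledDataset":
        """Same features, labels shuffled — a chance-level null dataset."""
        rng = np.random.default_rng(seed)
        y = self.y.copy()
        rng.shuffle(y)
        return replace_dataset(self, y=y)


def replace_dataset(d: LabeledDataset, **kw) -> LabeledDataset:
    fields = dict(
        y=d.y, subject_ids=d.subject_ids, sample_ids=d.sample_ids,
        X_bio=d.X_bio, X_emb=d.X_emb,
    )
    fields.update(kw)
    return LabeledDataset(**fields)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/validation/test index sets."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: Tuple[float, float, float]
    seed: int
    subject_wise: bool = True

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValidationError("split index sets must be disjoint")

    def assert_no_subject_leakage(self, subject_ids: np.ndarray) -> None:
        sets = [set(subject_ids[s]) for s in (self.train, self.val, self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValidationError(
                        f"subject leakage between split sets: {sets[i] & sets[j]}"
                    )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s in (self.train, self.val, self.test):
            h.update(np.sort(np.asarray(s)).tobytes())
        return h.hexdigest()[:16]


def subject_wise_split(
    data: LabeledDataset,
    fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Shuffle subjects and assign each greedily to the set with the
    largest remaining sample-count deficit.

    Assignment is stratified at the subject level (by each subject's
    majority label) so that every split sees both classes whenever the
    cohort allows it; within a label group, subjects go to the set whose
    per-label target is furthest from being met.
    """
    subjects = pd.unique(data.subject_ids)
    if len(subjects) < 3:
        raise ValidationError("subject-wise split needs at least 3 subjects")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = pd.Series(data.subject_ids).value_counts()
    subj_label = (
        pd.DataFrame({"subject": data.subject_ids, "y": data.y})
        .groupby("subject")["y"]
        .agg(lambda s: int(round(s.mean())))
    )
    assigned: List[List[str]] = [[], [], []]
    for label in sorted(subj_label.unique()):
        group = np.asarray(
            [s for s in subjects if subj_label[s] == label], dtype=object
        )
        group = group[rng.permutation(len(group))]
        group_n = float(sum(counts[s] for s in group))
        targets = [f * group_n for f in fractions]
        filled = [0.0, 0.0, 0.0]
        for subj in group:
            deficits = [targets[i] - filled[i] for i in range(3)]
            i = int(np.argmax(deficits))
            assigned[i].append(subj)
            filled[i] += counts[subj]
    # guarantee non-empty sets when a fraction is positive
    for i in range(3):
        if fractions[i] > 0 and not assigned[i]:
            donor = int(np.argmax([len(a) for a in assigned]))
            assigned[i].append(assigned[donor].pop())
    sets = [np.flatnonzero(np.isin(data.subject_ids, a)) for a in assigned]
    plan = SplitPlan(train=sets[0], val=sets[1], test=sets[2],
                     fractions=tuple(fractions), seed=seed, subject_wise=True)
    plan.assert_no_subject_leakage(data.subject_ids)
    return plan


def stratified_split(
    data: LabeledDataset, train_frac: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Sample-level label-stratified train/validation split (no test set).

    Provided for parity with protocols that report an 80/20 division;
    the subject-wise plan is the default because it is leakage-free.
    """
    rng = np.random.default_rng(seed)
    train, val = [], []
    for label in (0, 1):
        idx = np.flatnonzero(data.y == label)
        rng.shuffle(idx)
        cut = int(round(train_frac * idx.size))
        train.append(idx[:cut])
        val.append(idx[cut:])
    return SplitPlan(
        train=np.sort(np.concatenate(train)), val=np.sort(np.concatenate(val)),
        test=np.array([], dtype=int), fractions=(train_frac, 1 - train_frac, 0.0),
        seed=seed, subject_wise=False,
    )


def augment_features(
    m: np.ndarray, cfg: TrainingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with sd = feature_noise_frac x (per-feature range).

    The range is computed over the rows passed in (training rows only);
    constant columns are left unchanged.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape[0] < 2:
        raise ValidationError("feature augmentation needs >= 2 rows")
    if cfg.feature_noise_frac == 0:
        return m.copy()
    ranges = m.max(axis=0) - m.min(axis=0)
    return m + rng.normal(0.0, 1.0, m.shape) * (cfg.feature_noise_frac * ranges)


# --------------------------------------------------------------------------
# fitted model wrapper

@dataclass
class FittedModel:
    """A trained classifier plus the preprocessing fitted on its train split."""

    model: HybridFusionClassifier
    bio_stats: Optional[StandardizationStats]
    emb_stats: Optional[StandardizationStats]
    history: pd.DataFrame
    use_bio: bool = True
    use_emb: bool = True

    def features(self, data: LabeledDataset) -> np.ndarray:
        blocks = []
        if self.use_bio:
            if data.X_bio is None:
                raise DependencyError("model expects biomarkers; dataset has none")
            blocks.append(apply_standardization(data.X_bio, self.bio_stats))
        if self.use_emb:
            if data.X_emb is None:
                raise DependencyError("model expects embeddings; dataset has none")
            blocks.append(apply_standardization(data.X_emb, self.emb_stats))
        return np.concatenate(blocks, axis=1)

    def predict_proba(self, data: LabeledDataset) -> np.ndarray:
        return self.model.predict_proba(self.features(data))


def _block_dims(data: LabeledDataset, use_bio: bool, use_emb: bool) -> int:
    dim = 0
    if use_bio:
        dim += data.X_bio.shape[1]
    if use_emb:
        dim += data.X_emb.shape[1]
    return dim


def train(
    data: LabeledDataset,
    plan: SplitPlan,
    cfg: TrainingConfig,
    model_cfg: Optional[ClassifierConfig] = None,
    use_bio: bool = True,
    use_emb: bool = True,
) -> FittedModel:
    """Train the fusion classifier on the plan's train split.

    Standardization is fitted on training rows only and applied
    everywhere; biomarker rows are re-augmented with range-scaled noise
    each epoch; optimisation is Adam + cosine schedule with early
    stopping, returning the minimum-validation-loss checkpoint.
    """
    if plan.train.size == 0 or plan.val.size == 0:
        raise EmptyInputError("train and validation splits must be non-empty")
    if not (use_bio or use_emb):
        raise ValidationError("at least one modality must be enabled")
    if plan.subject_wise:
        plan.assert_no_subject_leakage(data.subject_ids)
    rng = np.random.default_rng(cfg.seed)

    bio_stats = emb_stats = None
    if use_bio:
        bio_stats = fit_standardization(data.X_bio[plan.train])
    if use_emb:
        emb_stats = fit_standardization(data.X_emb[plan.train])

    def assemble(idx: np.ndarray, augment: bool) -> np.ndarray:
        parts = []
        if use_bio:
            xb = data.X_bio[idx]
            if augment:
                xb = augment_features(xb, cfg, rng)
            parts.append(apply_standardization(xb, bio_stats))
        if use_emb:
            parts.append(apply_standardization(data.X_emb[idx], emb_stats))
        return np.concatenate(parts, axis=1)

    input_dim = _block_dims(data, use_bio, use_emb)
    if model_cfg is None:
        model_cfg = ClassifierConfig(input_dim=input_dim)
    elif model_cfg.input_dim != input_dim:
        model_cfg = replace(model_cfg, input_dim=input_dim)

    model = HybridFusionClassifier(model_cfg, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.eta_max,
               betas=(cfg.beta1, cfg.beta2), eps=cfg.eps_adam,
               weight_decay=cfg.weight_decay)

    X_val = assemble(plan.val, augment=False)
    y_val = data.y[plan.val]
    y_train = data.y[plan.train]

    best_loss = np.inf
    best_state = model.state_dict()
    since_best = 0
    rows = []
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(epoch, cfg)
        X_train = assemble(plan.train, augment=cfg.feature_noise_frac > 0 and use_bio)
        order = rng.permutation(len(y_train))
        model.train()
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs at least 2 rows
            proba = model.forward_tensor(Tensor(X_train[idx]))
            loss = cross_entropy_tensor(proba, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        model.eval()
        p_train = model.predict_proba(X_train)
        p_val = model.predict_proba(X_val)
        train_loss = cross_entropy(p_train, y_train)
        val_loss = cross_entropy(p_val, y_val)
        rows.append({
            "epoch": epoch, "lr": opt.lr,
            "train_loss": train_loss, "val_loss": val_loss,
            "train_acc": float(np.mean(np.argmax(p_train, 1) == y_train)),
            "val_acc": float(np.mean(np.argmax(p_val, 1) == y_val)),
        })
        if val_loss < best_loss - cfg.min_delta:
            best_loss = val_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return FittedModel(
        model=model, bio_stats=bio_stats, emb_stats=emb_stats,
        history=pd.DataFrame(rows), use_bio=use_bio, use_emb=use_emb,
    )


# --------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Test-set metrics, all recomputable from the confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    specificity: float
    confusion: np.ndarray            # [[TN, FP], [FN, TP]]
    confidences: np.ndarray          # (n, 2) class probabilities
    y_true: np.ndarray

    def to_dict(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "specificity": self.specificity,
        }


def metrics_from_confusion(confusion: np.ndarray) -> Dict[str, float]:
    """Accuracy/precision/recall/F1/specificity from a 2x2 matrix."""
    (tn, fp), (fn, tp) = np.asarray(confusion, dtype=float)
    total = tn + fp + fn + tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": (2 * precision * recall / (precision + recall)
               if precision + recall else 0.0),
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }


def report_from_scores(y_true: np.ndarray, proba: np.ndarray) -> EvalReport:
    """Build an EvalReport from true labels and class probabilities.

    AUC is the trapezoidal area under the ROC with the midpoint tie
    convention (a constant score gives 0.5); it is undefined for a
    single-class set.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=np.float64)
    if len(set(y_true)) < 2:
        raise ValidationError("AUC undefined: test set contains a single class")
    y_pred = np.argmax(proba, axis=1)
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    m = metrics_from_confusion(confusion)
    auc = float(roc_auc_score(y_true, proba[:, 1]))
    return EvalReport(
        accuracy=m["accuracy"], precision=m["precision"], recall=m["recall"],
        f1=m["f1"], auc=auc, specificity=m["specificity"],
        confusion=confusion, confidences=proba, y_true=y_true,
    )


def evaluate(
    fitted: FittedModel, data: LabeledDataset, plan: SplitPlan,
    split: str = "test",
) -> EvalReport:
    """Evaluate a fitted model on the plan's held-out split."""
    idx = getattr(plan, split)
    if idx.size == 0:
        raise EmptyInputError(f"{split} split is empty")
    subset = replace_dataset(
        data,
        y=data.y[idx], subject_ids=data.subject_ids[idx],
        sample_ids=data.sample_ids[idx],
        X_bio=None if data.X_bio is None else data.X_bio[idx],
        X_emb=None if data.X_emb is None else data.X_emb[idx],
    )
    proba = fitted.predict_proba(subset)
    return report_from_scores(subset.y, proba)


# --------------------------------------------------------------------------
# cross-validation

def _stratified_subject_folds(
    data: LabeledDataset, k: int, seed: int
) -> List[np.ndarray]:
    """Subject-wise folds, label-stratified by each subject's majority label."""
    df = pd.DataFrame({"subject": data.subject_ids, "y": data.y})
    subj_label = df.groupby("subject")["y"].agg(lambda s: int(round(s.mean())))
    subjects = subj_label.index.to_numpy()
    if len(subjects) < k:
        raise ValidationError(f"k={k} exceeds subject count {len(subjects)}")
    rng = np.random.default_rng(seed)
    folds: List[List[str]] = [[] for _ in range(k)]
    for label in (0, 1):
        group = subjects[subj_label.to_numpy() == label]
        group = group[rng.permutation(len(group))]
        for i, subj in enumerate(group):
            folds[i % k].append(subj)
    return [np.flatnonzero(np.isin(data.subject_ids, f)) for f in folds]


def cross_validate(
    data: LabeledDataset,
    k: int,
    cfg: TrainingConfig,
    model_cfg: Optional[ClassifierConfig] = None,
    use_bio: bool = True,
    use_emb: bool = True,
) -> Tuple[List[EvalReport], Dict[str, float]]:
    """Subject-wise, subject-label-stratified k-fold cross-validation.

    Each fold's subjects form the test set once; the remaining subjects
    are split again subject-wise to give a validation set for early
    stopping.  Returns per-fold reports plus mean/variance summaries.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    folds = _stratified_subject_folds(data, k, cfg.seed)
    reports = []
    all_idx = np.arange(len(data))
    for i, test_idx in enumerate(folds):
        rest = np.setdiff1d(all_idx, test_idx)
        rest_data = replace_dataset(
            data,
            y=data.y[rest], subject_ids=data.subject_ids[rest],
            sample_ids=data.sample_ids[rest],
            X_bio=None if data.X_bio is None else data.X_bio[rest],
            X_emb=None if data.X_emb is None else data.X_emb[rest],
        )
        inner = subject_wise_split(rest_data, (0.85, 0.15, 0.0), seed=cfg.seed + i)
        fitted = train(rest_data, inner, replace(cfg, seed=cfg.seed + i),
                       model_cfg=model_cfg, use_bio=use_bio, use_emb=use_emb)
        test_data = replace_dataset(
            data,
            y=data.y[test_idx], subject_ids=data.subject_ids[test_idx],
            sample_ids=data.sample_ids[test_idx],
            X_bio=None if data.X_bio is None else data.X_bio[test_idx],
            X_emb=None if data.X_emb is None else data.X_emb[test_idx],
        )
        reports.append(report_from_scores(test_data.y, fitted.predict_proba(test_data)))
    accs = [r.accuracy for r in reports]
    summary = {
        "mean_accuracy": float(np.mean(accs)),
        "var_accuracy": float(np.var(accs)),
        "mean_f1": float(np.mean([r.f1 for r in reports])),
        "mean_auc": float(np.mean([r.auc for r in reports])),
    }
    return reports, summary


# --------------------------------------------------------------------------
# ablation grid

_ABLATION_MODIFIERS = {
    "full", "drop_biomarkers", "drop_embeddings", "no_batch_norm",
    "no_dropout", "late_fusion_voting", "logistic_baseline",
}


def run_ablation(
    data: LabeledDataset,
    grid: Sequence[str],
    cfg: TrainingConfig,
    plan: Optional[SplitPlan] = None,
    model_cfg: Optional[ClassifierConfig] = None,
) -> pd.DataFrame:
    """One EvalReport row per named configuration under one shared split.

    Config names: ``full``, ``drop_biomarkers``, ``drop_embeddings``,
    ``no_batch_norm``, ``no_dropout``, ``late_fusion_voting``,
    ``logistic_baseline``; modifiers can be combined with ``+``
    (dropping both modalities is a config error).
    """
    plan = plan or subject_wise_split(data, seed=cfg.seed)
    base_cfg = model_cfg or ClassifierConfig(
        input_dim=_block_dims(data, True, True)
    )
    rows = []
    for name in grid:
        mods = set(name.split("+"))
        unknown = mods - _ABLATION_MODIFIERS
        if unknown:
            raise ValidationError(f"unknown ablation configuration(s) {unknown}")
        if {"drop_biomarkers", "drop_embeddings"} <= mods:
            raise ValidationError("cannot drop both modalities")
        use_bio = "drop_biomarkers" not in mods
        use_emb = "drop_embeddings" not in mods
        mcfg = base_cfg
        if "no_batch_norm" in mods:
            mcfg = replace(mcfg, use_batch_norm=False)
        if "no_dropout" in mods:
            mcfg = replace(mcfg, dropout=0.0)

        if "logistic_baseline" in mods:
            clf = LogisticRegression(max_iter=1000, random_state=cfg.seed)
            stats = fit_standardization(data.X_bio[plan.train])
            clf.fit(apply_standardization(data.X_bio[plan.train], stats),
                    data.y[plan.train])
            proba = clf.predict_proba(
                apply_standardization(data.X_bio[plan.test], stats)
            )
            report = report_from_scores(data.y[plan.test], proba)
        elif "late_fusion_voting" in mods:
            fitted_b = train(data, plan, cfg, model_cfg=mcfg,
                             use_bio=True, use_emb=False)
            fitted_e = train(data, plan, cfg, model_cfg=mcfg,
                             use_bio=False, use_emb=True)
            test = replace_dataset(
                data,
                y=data.y[plan.test], subject_ids=data.subject_ids[plan.test],
                sample_ids=data.sample_ids[plan.test],
                X_bio=data.X_bio[plan.test], X_emb=data.X_emb[plan.test],
            )
            proba = 0.5 * (fitted_b.predict_proba(test) + fitted_e.predict_proba(test))
            report = report_from_scores(test.y, proba)
        else:
            fitted = train(data, plan, cfg, model_cfg=mcfg,
                           use_bio=use_bio, use_emb=use_emb)
            report = evaluate(fitted, data, plan)
        rows.append({"config": name, **report.to_dict(),
                     "split_hash": plan.content_hash()})
    return pd.DataFrame(rows)
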