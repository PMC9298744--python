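"""Subject-level cross-validated training and evaluation.

The protocol guards against identity leakage: subjects owning a baseline
(enrollment) scan are partitioned into k near-equal subsets; in each fold the
held-out subset contributes ONLY its baseline scans to the test set, while
all scans of the remaining subjects — plus all scans of subjects without a
baseline — form the training pool, from which a subject-level validation
split is carved.  Scans of one subject therefore never straddle the
train/test boundary, and follow-up scans of held-out subjects are used
nowhere in that fold.

Training minimises softmax cross-entropy with Adam (recommended defaults),
records train/validation loss per epoch, and keeps the weights from the
epoch with minimal validation loss for testing.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import model as M
from .dfc import SlidingWindowConfig, build_dfc
from .io_cohort import LABEL_TO_INDEX, Cohort

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    """Scan-id assignment of one cross-validation fold."""

    fold_index: int
    train_scan_ids: set[str]
    val_scan_ids: set[str]
    test_scan_ids: set[str]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters: Adam with recommended defaults,
    200 epochs, batch size 16."""

    epochs: int = 200
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def make_subject_level_folds(
    cohort: Cohort, k: int = 5, val_frac: float = 0.2, seed: int = 0
) -> list[FoldSplit]:
    """Partition a cohort into k subject-level folds.

    Subjects with a baseline scan are shuffled (seeded) and dealt round-robin
    into k subsets whose sizes differ by at most one.  Per fold: the held-out
    subset's baseline scans are the test set; every scan of the remaining
    subjects and of subjects without a baseline is the training pool; a
    ``val_frac`` fraction of training SUBJECTS (not scans) is moved to the
    validation set.
    """
    subj_scans: dict[str, list] = {}
    for r in cohort.records:
        subj_scans.setdefault(r.subject_id, []).append(r)
    with_baseline = [s for s, recs in subj_scans.items() if any(r.is_baseline for r in recs)]
    without_baseline = [s for s in subj_scans if s not in set(with_baseline)]
    if len(with_baseline) < k:
        raise ValueError(
            f"need at least {k} subjects with baseline scans, have {len(with_baseline)}"
        )
    rng = np.random.default_rng(seed)
    order = [with_baseline[i] for i in rng.permutation(len(with_baseline))]
    subsets: list[list[str]] = [order[i::k] for i in range(k)]

    folds = []
    for f in range(k):
        test_subjects = subsets[f]
        test_ids = {
            r.scan_id for s in test_subjects for r in subj_scans[s] if r.is_baseline
        }
        pool = [s for g in range(k) if g != f for s in subsets[g]] + list(without_baseline)
        n_val = max(1, int(round(val_frac * len(pool)))) if val_frac > 0 else 0
        val_pick = set(
            pool[i] for i in rng.permutation(len(pool))[:n_val]
        )
        train_ids = {r.scan_id for s in pool if s not in val_pick for r in subj_scans[s]}
        val_ids = {r.scan_id for s in val_pick for r in subj_scans[s]}
        folds.append(
            FoldSplit(
                fold_index=f,
                train_scan_ids=train_ids,
                val_scan_ids=val_ids,
                test_scan_ids=test_ids,
            )
        )
    return folds


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class LabelCoding:
    """Mapping between cohort label strings and contiguous class indices.

    Classes are ordered by disease stage (NC < eMCI < lMCI < AD); for binary
    tasks the patient class (index 1) is the positive class for
    sensitivity/ROC purposes.
    """

    classes: list[str]

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "LabelCoding":
        present = sorted({r.label for r in cohort.records}, key=LABEL_TO_INDEX.get)
        return cls(classes=present)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def positive_class(self) -> str:
        if self.n_classes != 2:
            raise ValueError("positive class is defined for binary tasks only")
        return self.classes[1]

    def encode(self, label: str) -> int:
        return self.classes.index(label)


def subset_cohort(cohort: Cohort, labels: list[str]) -> Cohort:
    """Restrict a cohort to scans whose label is in ``labels``."""
    keep = [r for r in cohort.records if r.label in labels]
    ids = {r.scan_id for r in keep}
    return Cohort(records=keep, series={i: cohort.series[i] for i in ids})


def build_dfc_dataset(
    cohort: Cohort, window_config: SlidingWindowConfig
) -> tuple[dict[str, np.ndarray], dict[str, int], LabelCoding]:
    """Build the per-scan dFC tensors and class indices for a cohort."""
    coding = LabelCoding.from_cohort(cohort)
    tensors = {
        sid: build_dfc(ts, window_config).values for sid, ts in cohort.series.items()
    }
    labels = {r.scan_id: coding.encode(r.label) for r in cohort.records}
    return tensors, labels, coding


def _stack(tensors, labels, ids: set[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ordered = sorted(ids)
    X = np.stack([tensors[i] for i in ordered])
    y = np.array([labels[i] for i in ordered], dtype=int)
    return X, y, ordered


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: dict[str, np.ndarray]
    history: dict
    config: "M.CrnnConfig"


def fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    crnn_config: M.CrnnConfig,
    train_config: TrainConfig,
) -> FitResult:
    """Train one model, retaining the weights of the best-validation epoch."""
    present = np.unique(y_train)
    if len(present) < crnn_config.n_classes:
        raise ValueError(
            f"training data covers classes {present.tolist()} but the model "
            f"expects {crnn_config.n_classes}"
        )
    rng = np.random.default_rng(train_config.seed)
    params = M.init_params(crnn_config, n_rois=X_train.shape[2], rng=rng)
    opt = M.adam_init(params, lr=train_config.lr)
    n = len(y_train)
    train_losses, val_losses = [], []
    best = (np.inf, copy.deepcopy(params), -1)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            loss, grads, _ = M.loss_and_grads(
                X_train[idx], y_train[idx], params, crnn_config, train=True, rng=rng
            )
            M.adam_step(params, grads, opt)
            batch_losses.append(loss)
        train_losses.append(float(np.mean(batch_losses)))
        val_probs, _ = M.forward(X_val, params, crnn_config, train=False)
        val_loss = M.cross_entropy(val_probs, y_val)
        val_losses.append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(params), epoch)
    history = {
        "train_loss": train_losses,
        "val_loss": val_losses,
        "best_epoch": best[2],
        "converged": best[2] < train_config.epochs - 1,
    }
    return FitResult(params=best[1], history=history, config=crnn_config)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def binary_metrics(y_true, y_pred) -> dict[str, float]:
    """ACC/SEN/SPE in percent; positive (patient) class coded 1.

    SEN (SPE) is NaN with a warning when no positive (negative) samples exist.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = 100.0 * (tp + tn) / len(y_true)
    if tp + fn == 0:
        warnings.warn("no positive samples: sensitivity undefined")
        sen = float("nan")
    else:
        sen = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples: specificity undefined")
        spe = float("nan")
    else:
        spe = 100.0 * tn / (tn + fp)
    return {"acc": acc, "sen": sen, "spe": spe}


def multiclass_metrics(y_true, y_pred, n_classes: int) -> dict:
    """Overall accuracy plus per-class accuracy (recall), in percent."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    overall = 100.0 * float(np.mean(y_true == y_pred))
    per_class = []
    for c in range(n_classes):
        mask = y_true == c
        per_class.append(100.0 * float(np.mean(y_pred[mask] == c)) if mask.any() else float("nan"))
    return {"acc": overall, "per_class_acc": per_class}


def roc_points(y_true, scores) -> dict:
    """ROC curve (thresholds swept over the scores) and trapezoid AUC."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present in y_true")
    fpr, tpr, thresholds = _sk_roc_curve(y_true, np.asarray(scores, dtype=float))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": float(_sk_auc(fpr, tpr))}


def summarize_folds(per_fold: list[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Mean +/- SD of each scalar metric across folds (NaNs ignored)."""
    keys = per_fold[0].keys()
    out = {}
    for k in keys:
        vals = np.array([f[k] for f in per_fold], dtype=float)
        out[k] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return out


# ---------------------------------------------------------------------------
# Cross-validation orchestration
# ---------------------------------------------------------------------------

@dataclass
class FoldOutcome:
    fold: FoldSplit
    fit: FitResult
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    probs: np.ndarray
    metrics: dict


@dataclass
class CVResult:
    coding: LabelCoding
    outcomes: list[FoldOutcome] = field(default_factory=list)

    @property
    def per_fold_metrics(self) -> list[dict]:
        return [
            {k: v for k, v in o.metrics.items() if np.isscalar(v)} for o in self.outcomes
        ]

    @property
    def summary(self) -> dict:
        return summarize_folds(self.per_fold_metrics)

    @property
    def mean_accuracy(self) -> float:
        return self.summary["acc"][0]


def cross_validate(
    cohort: Cohort,
    window_config: SlidingWindowConfig,
    crnn_config: M.CrnnConfig,
    train_config: TrainConfig,
    k: int = 5,
    val_frac: float = 0.2,
) -> CVResult:
    """Run the full subject-level k-fold protocol on an analysis-ready cohort."""
    tensors, labels, coding = build_dfc_dataset(cohort, window_config)
    if crnn_config.n_classes != coding.n_classes:
        crnn_config = replace(crnn_config, n_classes=coding.n_classes)
    folds = make_subject_level_folds(cohort, k=k, val_frac=val_frac, seed=train_config.seed)
    result = CVResult(coding=coding)
    for fold in folds:
        X_tr, y_tr, _ = _stack(tensors, labels, fold.train_scan_ids)
        X_va, y_va, _ = _stack(tensors, labels, fold.val_scan_ids)
        X_te, y_te, te_ids = _stack(tensors, labels, fold.test_scan_ids)
        fold_cfg = TrainConfig(
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            lr=train_config.lr,
            seed=train_config.seed + fold.fold_index,
        )
        fitres = fit(X_tr, y_tr, X_va, y_va, crnn_config, fold_cfg)
        probs, _ = M.forward(X_te, fitres.params, crnn_config, train=False)
        y_pred = probs.argmax(axis=1)
        if coding.n_classes == 2:
            metrics = binary_metrics(y_te, y_pred)
            try:
                metrics["auc"] = roc_points(y_te, probs[:, 1])["auc"]
            except ValueError:
                metrics["auc"] = float("nan")
        else:
            mm = multiclass_metrics(y_te, y_pred, coding.n_classes)
            metrics = {"acc": mm["acc"]}
            for i, c in enumerate(coding.classes):
                metrics[f"acc_{c}"] = mm["per_class_acc"][i]
        logger.info("fold %d: %s", fold.fold_index, metrics)
        result.outcomes.append(
            FoldOutcome(
                fold=fold,
                fit=fitres,
                test_ids=te_ids,
                y_true=y_te,
                y_pred=y_pred,
                probs=probs,
                metrics=metrics,
            )
        )
    return result
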