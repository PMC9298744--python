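"""Stationary-FC comparison methods.

Two classical pipelines the network is compared against, both built on the
whole-series (stationary) correlation network of each scan:

* "strength": the N(N-1)/2 upper-triangle correlation values are the
  features (6,670 for a 116-ROI atlas);
* "cc": one weighted local clustering coefficient per node (Onnela
  formula on absolute, max-normalised weights).

Either feature set goes through two-sample t-test selection (p < 0.05,
fitted on training data only) and a linear SVM with default parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dfc import pearson_matrix
from .io_cohort import Cohort, RoiTimeSeries
from .train import (
    FoldSplit,
    LabelCoding,
    binary_metrics,
    multiclass_metrics,
    roc_points,
    summarize_folds,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    scan_id: str
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.feature_names):
            raise ValueError("feature values and names differ in length")


def static_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Stationary FC: Pearson correlation over the entire (trimmed) series.

    Identical to the single slice of the dFC tensor built with L = M.
    """
    return pearson_matrix(ts.values)


def upper_triangle_features(fc: np.ndarray, scan_id: str = "") -> FeatureVector:
    """Strictly-upper-triangle entries in row-major pair order (0,1),(0,2),..."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {fc.shape}")
    iu = np.triu_indices(fc.shape[0], k=1)
    names = [f"r_{i}_{j}" for i, j in zip(*iu)]
    return FeatureVector(scan_id=scan_id, values=fc[iu], feature_names=names)


def clustering_coefficients(fc: np.ndarray, scan_id: str = "") -> FeatureVector:
    """Weighted local clustering coefficient of every node.

    Onnela's formula on w_hat = |w| / max|w| with the diagonal excluded:
    C_i = (k_i (k_i - 1))^-1 * sum_{j,h} (w_hat_ij w_hat_jh w_hat_hi)^(1/3).
    Scale-invariant by construction.  Returns zeros (with a warning) for
    networks of fewer than 3 nodes.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {fc.shape}")
    n = fc.shape[0]
    names = [f"cc_{i}" for i in range(n)]
    if n < 3:
        warnings.warn("clustering coefficients undefined for < 3 nodes; returning zeros")
        return FeatureVector(scan_id=scan_id, values=np.zeros(n), feature_names=names)
    w = np.abs(fc).astype(float)
    np.fill_diagonal(w, 0.0)
    g = nx.from_numpy_array(w)
    # networkx's weighted clustering is the Onnela coefficient with weights
    # normalised by the maximum; edges of weight 0 are absent from the graph
    cc = nx.clustering(g, weight="weight")
    return FeatureVector(
        scan_id=scan_id, values=np.array([cc[i] for i in range(n)]), feature_names=names
    )


def ttest_select(
    features: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sample t-test selection for a binary task.

    Returns (keep mask, p-values).  Degenerate features get p = 1.  If no
    feature survives, the single smallest-p feature is kept with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("t-test selection needs two classes")
    if len(classes) > 2:
        raise ValueError("binary selection called with more than two classes")
    a = features[labels == classes[0]]
    b = features[labels == classes[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    keep = p < alpha
    if not keep.any():
        warnings.warn("no feature below alpha; keeping the single smallest-p feature")
        keep = np.zeros_like(keep)
        keep[np.argmin(p)] = True
    return keep, p


def ttest_select_ovr(
    features: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-class selection: union of one-vs-rest binary selections."""
    labels = np.asarray(labels, dtype=int)
    keep = np.zeros(features.shape[1], dtype=bool)
    p_min = np.ones(features.shape[1])
    for c in np.unique(labels):
        k, p = ttest_select(features, (labels == c).astype(int), alpha=alpha)
        keep |= k
        p_min = np.minimum(p_min, p)
    return keep, p_min


def linear_svm_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardise (train statistics), drop constant features, fit a linear
    SVM with default regularisation; return predictions and decision scores."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    live = X_train.std(axis=0) > 0
    if not live.all():
        warnings.warn(f"dropping {int((~live).sum())} constant feature(s)")
        X_train, X_test = X_train[:, live], X_test[:, live]
    scaler = StandardScaler().fit(X_train)
    clf = SVC(kernel="linear")
    clf.fit(scaler.transform(X_train), y_train)
    Xt = scaler.transform(X_test)
    return clf.predict(Xt), clf.decision_function(Xt)


# ---------------------------------------------------------------------------
# Cross-validated baseline runs
# ---------------------------------------------------------------------------

def scan_features(cohort: Cohort, method: str) -> dict[str, np.ndarray]:
    """Stationary-FC feature vector per scan ('strength' or 'cc')."""
    if method not in ("strength", "cc"):
        raise ValueError(f"unknown baseline method {method!r}")
    out = {}
    for sid, ts in cohort.series.items():
        fc = static_fc(ts)
        fv = upper_triangle_features(fc, sid) if method == "strength" else clustering_coefficients(fc, sid)
        out[sid] = fv.values
    return out


def baseline_cross_validate(
    cohort: Cohort,
    folds: list[FoldSplit],
    method: str = "strength",
    alpha: float = 0.05,
) -> dict:
    """Run a stationary-FC baseline through the subject-level CV protocol.

    Feature selection is fitted per fold on the training scans only (the
    validation split is folded back into training — the SVM has no epochs to
    tune).  Returns per-fold metrics and their mean +/- SD summary.
    """
    coding = LabelCoding.from_cohort(cohort)
    feats = scan_features(cohort, method)
    labels = {r.scan_id: coding.encode(r.label) for r in cohort.records}
    per_fold = []
    fold_details = []
    for fold in folds:
        train_ids = sorted(fold.train_scan_ids | fold.val_scan_ids)
        test_ids = sorted(fold.test_scan_ids)
        X_tr = np.stack([feats[i] for i in train_ids])
        y_tr = np.array([labels[i] for i in train_ids])
        X_te = np.stack([feats[i] for i in test_ids])
        y_te = np.array([labels[i] for i in test_ids])
        select = ttest_select if coding.n_classes == 2 else ttest_select_ovr
        keep, _ = select(X_tr, y_tr, alpha=alpha)
        y_pred, scores = linear_svm_fit_predict(X_tr[:, keep], y_tr, X_te[:, keep])
        if coding.n_classes == 2:
            metrics = binary_metrics(y_te, y_pred)
            try:
                metrics["auc"] = roc_points(y_te, scores)["auc"]
            except ValueError:
                metrics["auc"] = float("nan")
        else:
            mm = multiclass_metrics(y_te, y_pred, coding.n_classes)
            metrics = {"acc": mm["acc"]}
            for i, c in enumerate(coding.classes):
                metrics[f"acc_{c}"] = mm["per_class_acc"][i]
        logger.info("baseline(%s) fold %d: %s", method, fold.fold_index, metrics)
        per_fold.append(metrics)
        fold_details.append(
            {"fold": fold.fold_index, "n_selected": int(keep.sum()), "y_true": y_te, "y_pred": y_pred}
        )
    return {
        "method": method,
        "coding": coding,
        "per_fold": per_fold,
        "summary": summarize_folds(per_fold),
        "details": fold_details,
    }


def expected_feature_count(n_rois: int, method: str) -> int:
    """Dimensionality of each baseline's feature space (6,670 strength
    features or 116 clustering coefficients for the 116-ROI atlas)."""
    if method == "strength":
        return n_rois * (n_rois - 1) // 2
    if method == "cc":
        return n_rois
    raise ValueError(f"unknown baseline method {method!r}")
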