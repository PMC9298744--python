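"""Discriminative region and connectivity discovery from trained models.

After cross-validated training, the first convolutional layer's activations
are turned into per-ROI feature vectors (time-averaged over the T-1 output
positions, one vector per channel), and two-sample t-tests locate ROIs whose
features differ between diagnostic groups.  A region counts as
discriminative when its p-value falls below alpha in at least ``min_folds``
of the cross-validation folds (default 3 of 5), evaluated per channel.
Between selected regions, group differences in connectivity strength (the
per-subject mean over windows of a dFC edge) are mapped, with
non-significant p-values displayed as 1 for clarity.  Finally, the
discriminative power of the learned sequence-stage features (64 LSTM
features, or 32 pooled features for the CNN ablation) is summarised as the
mean and median of their per-feature p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources as importlib_resources

import numpy as np
from scipy import stats

from . import model as M
from .dfc import SlidingWindowConfig, build_dfc
from .io_cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass
class ChannelFeatureMatrix:
    """Per-channel region features: one row per scan, one column per ROI."""

    channel: int
    matrix: np.ndarray
    scan_ids: list[str]


@dataclass
class RegionSelection:
    channel: int
    roi_index: int
    p_per_fold: list[float]
    n_significant: int
    selected: bool


@dataclass
class ConnectivityDifferenceMap:
    """Pairwise group-difference p-values between selected regions.

    ``p_display`` replaces p > alpha by 1 (a common display convention);
    ``p_raw`` keeps the untouched values for quantitative use.
    """

    roi_indices: list[int]
    p_raw: np.ndarray
    p_display: np.ndarray
    alpha: float = 0.05


@dataclass
class FeaturePowerReport:
    p_values: np.ndarray
    mean_p: float
    median_p: float


# ---------------------------------------------------------------------------
# Feature extraction from trained models
# ---------------------------------------------------------------------------

def extract_region_features(
    params: dict[str, np.ndarray],
    config: M.CrnnConfig,
    X: np.ndarray,
    scan_ids: list[str] | None = None,
) -> list[ChannelFeatureMatrix]:
    """Time-averaged conv1 activations: K1 matrices of shape (scans, N).

    conv1's output is (T-S1+1, 1, N, K1) per scan; averaging over the time
    positions yields one N-vector per channel and scan.
    """
    if not isinstance(params, dict) or "W1" not in params:
        raise ValueError("extract_region_features requires trained model parameters")
    _, cache = M.conv_features(np.asarray(X, dtype=float), params, config)
    out1 = cache["out1"]  # (B, T-S1+1, N, K1)
    mean_feat = out1.mean(axis=1)  # (B, N, K1)
    ids = scan_ids or [f"scan_{i}" for i in range(mean_feat.shape[0])]
    return [
        ChannelFeatureMatrix(channel=c, matrix=mean_feat[:, :, c], scan_ids=list(ids))
        for c in range(config.k1)
    ]


def extract_sequence_features(
    params: dict[str, np.ndarray], config: M.CrnnConfig, X: np.ndarray
) -> np.ndarray:
    """The learned scan representation entering the classifier head
    (final LSTM hidden state, or the pooled K3-vector for the ablation)."""
    seq, _ = M.conv_features(np.asarray(X, dtype=float), params, config)
    feat, _ = M.sequence_features(seq, params, config)
    return feat


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student pooled-variance by default;
    pass equal_var=False for Welch).  Zero pooled variance yields (0, 1)
    with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std() == 0.0 and b.std() == 0.0:
        warnings.warn("zero pooled variance; reporting p = 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def select_regions(
    p_table: np.ndarray, alpha: float = 0.05, min_folds: int = 3
) -> list[RegionSelection]:
    """Apply the repetition rule to a (channels, rois, folds) p-value table.

    A (channel, roi) pair is selected iff its p-value is below ``alpha`` in
    at least ``min_folds`` folds.  Missing (NaN) entries are an error.
    """
    p_table = np.asarray(p_table, dtype=float)
    if p_table.ndim != 3:
        raise ValueError("p_table must have shape (channels, rois, folds)")
    if np.isnan(p_table).any():
        raise ValueError("p_table contains missing fold entries")
    selections = []
    for c in range(p_table.shape[0]):
        for r in range(p_table.shape[1]):
            p = p_table[c, r]
            n_sig = int(np.sum(p < alpha))
            selections.append(
                RegionSelection(
                    channel=c,
                    roi_index=r,
                    p_per_fold=[float(x) for x in p],
                    n_significant=n_sig,
                    selected=n_sig >= min_folds,
                )
            )
    return selections


def selected_rois(selections: list[RegionSelection]) -> list[int]:
    """Union over channels of selected ROI indices (sorted)."""
    return sorted({s.roi_index for s in selections if s.selected})


def region_pvalue_table(
    fold_params: list[dict[str, np.ndarray]],
    config: M.CrnnConfig,
    X: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Per-fold region p-values: for each fold's trained model, extract
    conv1 region features of all scans and t-test group 0 vs group 1 per
    (channel, ROI).  Returns shape (K1, N, n_folds)."""
    y = np.asarray(y, dtype=int)
    n_folds = len(fold_params)
    N = X.shape[2]
    table = np.empty((config.k1, N, n_folds))
    for f, params in enumerate(fold_params):
        channels = extract_region_features(params, config, X)
        for c, chan in enumerate(channels):
            a = chan.matrix[y == 0]
            b = chan.matrix[y == 1]
            for r in range(N):
                table[c, r, f] = two_sample_ttest(a[:, r], b[:, r])[1]
    return table


# ---------------------------------------------------------------------------
# Connectivity differences between selected regions
# ---------------------------------------------------------------------------

def connectivity_strengths(
    cohort: Cohort,
    window_config: SlidingWindowConfig,
    rois: list[int] | None = None,
    use_static: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-subject connectivity strengths: mean over the T windows of each
    dFC edge (or the stationary correlation when ``use_static``).

    One scan represents each subject: the baseline scan when present,
    otherwise the subject's first scan.  Returns (edge matrix stack of shape
    (subjects, N, N), group index per subject, subject ids).
    """
    chosen = []
    for sid in cohort.subject_ids:
        rec = cohort.baseline_scan(sid) or cohort.scans_of(sid)[0]
        chosen.append(rec)
    labels = sorted({r.label for r in chosen})
    strengths, groups, subjects = [], [], []
    for rec in chosen:
        ts = cohort.series[rec.scan_id]
        if use_static:
            from .baselines import static_fc

            mat = static_fc(ts)
        else:
            mat = build_dfc(ts, window_config).values.mean(axis=0)
        strengths.append(mat)
        groups.append(labels.index(rec.label))
        subjects.append(rec.subject_id)
    return np.stack(strengths), np.asarray(groups), subjects


def connectivity_group_difference(
    cohort: Cohort,
    rois: list[int],
    window_config: SlidingWindowConfig,
    alpha: float = 0.05,
    use_static: bool = False,
) -> ConnectivityDifferenceMap:
    """T-test the connectivity strength of every selected-region pair
    between the two groups of the cohort."""
    rois = sorted(rois)
    k = len(rois)
    if k < 2:
        warnings.warn("fewer than 2 selected regions; empty connectivity map")
        return ConnectivityDifferenceMap(
            roi_indices=rois, p_raw=np.ones((k, k)), p_display=np.ones((k, k)), alpha=alpha
        )
    strengths, groups, _ = connectivity_strengths(cohort, window_config, use_static=use_static)
    if len(np.unique(groups)) != 2:
        raise ValueError("connectivity difference needs exactly two groups")
    p_raw = np.ones((k, k))
    for ii in range(k):
        for jj in range(ii + 1, k):
            a = strengths[groups == 0, rois[ii], rois[jj]]
            b = strengths[groups == 1, rois[ii], rois[jj]]
            _, p = two_sample_ttest(a, b)
            p_raw[ii, jj] = p_raw[jj, ii] = p
    p_display = np.where(p_raw > alpha, 1.0, p_raw)
    return ConnectivityDifferenceMap(
        roi_indices=rois, p_raw=p_raw, p_display=p_display, alpha=alpha
    )


def feature_power(features: np.ndarray, labels: np.ndarray) -> FeaturePowerReport:
    """Discriminative power of learned features: per-feature two-sided
    t-test p-values between the two groups, with their mean and median."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("feature power is defined for two groups")
    p_values = np.empty(features.shape[1])
    for j in range(features.shape[1]):
        a = features[labels == classes[0], j]
        b = features[labels == classes[1], j]
        if a.std() == 0.0 and b.std() == 0.0:
            warnings.warn(f"feature {j} degenerate; p = 1")
            p_values[j] = 1.0
        else:
            p_values[j] = stats.ttest_ind(a, b, equal_var=True)[1]
    return FeaturePowerReport(
        p_values=p_values,
        mean_p=float(np.mean(p_values)),
        median_p=float(np.median(p_values)),
    )


# ---------------------------------------------------------------------------
# Region naming
# ---------------------------------------------------------------------------

def roi_labels(n_rois: int) -> list[str]:
    """Anatomical names for the 116-region AAL atlas; generic ROI_### labels
    for any other parcellation size (synthetic cohorts)."""
    if n_rois == 116:
        text = (
            importlib_resources.files("dfcrnn.resources")
            .joinpath("aal116_labels.txt")
            .read_text()
        )
        labels = [line.strip() for line in text.splitlines() if line.strip()]
        if len(labels) != 116:
            raise RuntimeError("AAL label resource corrupted")
        return labels
    return [f"ROI_{i + 1:03d}" for i in range(n_rois)]
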