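"""Seeded synthetic rs-fMRI cohorts for end-to-end testing of the pipeline.

Each subject's ROI time series is a concatenation of zero-mean multivariate
Gaussian segments — one per covariance "state" in the subject's group
schedule — plus isotropic measurement noise.  Because every downstream stage
(windowed correlation, conv/LSTM features, t-tests) consumes only
second-order statistics of the signals, this generator can pose all the
regimes the method distinguishes:

* separable — groups differ in stationary covariance (effect edges with a
  known correlation delta);
* sequence-only — groups share the same SET of states but visit them in
  opposite order, so stationary FC matches while the windowed sequence
  differs (only an order-aware model can separate them);
* null — both groups identically distributed (for type-I error studies).

Cohorts mirror the multi-scan structure of longitudinal studies: subjects
may own follow-up scans, and a small fraction lacks a baseline scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_cohort import Cohort, LABELS, RoiTimeSeries, ScanRecord

#: Study-condition defaults: cohort geometry and effect size.
DEFAULT_N_SUBJECTS = 20
DEFAULT_N_ROIS = 30
DEFAULT_N_TIMEPOINTS = 140
DEFAULT_DELTA = 0.5
DEFAULT_NOISE_SD = 0.2
DEFAULT_MULTI_SCAN_PROB = 0.3
DEFAULT_BASELINE_MISSING_PROB = 0.1
DEFAULT_BACKGROUND_RHO = 0.1


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic cohort (all randomness seeded)."""

    state_covariances: dict[str, np.ndarray]
    state_schedule_per_group: dict[str, list[tuple[str, int]]]
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS
    n_rois: int = DEFAULT_N_ROIS
    n_timepoints: int = DEFAULT_N_TIMEPOINTS
    effect_edges: list[tuple[int, int]] = field(default_factory=list)
    delta: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    multi_scan_prob: float = DEFAULT_MULTI_SCAN_PROB
    baseline_missing_prob: float = DEFAULT_BASELINE_MISSING_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cov in self.state_covariances.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.n_rois, self.n_rois):
                raise ValueError(f"state {name!r}: covariance shape {cov.shape} != n_rois")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"state {name!r}: covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"state {name!r}: covariance not positive definite")
            self.state_covariances[name] = cov
        for group, schedule in self.state_schedule_per_group.items():
            if group not in LABELS:
                raise ValueError(f"unknown group label {group!r}")
            total = sum(d for _, d in schedule)
            if total != self.n_timepoints:
                raise ValueError(
                    f"group {group!r}: schedule sums to {total}, expected {self.n_timepoints}"
                )
            for state, _ in schedule:
                if state not in self.state_covariances:
                    raise ValueError(f"group {group!r}: undefined state {state!r}")

    @property
    def groups(self) -> list[str]:
        return list(self.state_schedule_per_group)


def exchangeable_correlation(n: int, rho: float = DEFAULT_BACKGROUND_RHO) -> np.ndarray:
    """Correlation matrix with constant off-diagonal rho (SPD for rho > -1/(n-1))."""
    return np.full((n, n), rho) + (1.0 - rho) * np.eye(n)


def make_group_covariance(
    base: np.ndarray, effect_edges: list[tuple[int, int]], delta: float
) -> np.ndarray:
    """Shift selected correlations of ``base`` by ``delta`` and return an SPD
    correlation matrix.

    The shift is applied symmetrically; if it breaks positive definiteness,
    eigenvalues are clipped at 1e-6 and the matrix is rescaled to unit
    diagonal.
    """
    base = np.asarray(base, dtype=float)
    if not np.allclose(base, base.T):
        raise ValueError("base covariance must be symmetric")
    cov = base.copy()
    for i, j in effect_edges:
        if i == j:
            raise ValueError("effect edges must connect distinct ROIs")
        cov[i, j] += delta
        cov[j, i] += delta
    w, v = np.linalg.eigh(cov)
    if w.min() <= 1e-6:
        w = np.clip(w, 1e-6, None)
        cov = (v * w) @ v.T
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def _default_effect_edges(n_pairs: int = 10) -> list[tuple[int, int]]:
    # disjoint ROI pairs keep the SPD projection trivial and the ground truth clean
    return [(2 * i, 2 * i + 1) for i in range(n_pairs)]


def separable_config(
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS,
    n_rois: int = DEFAULT_N_ROIS,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    delta: float = DEFAULT_DELTA,
    seed: int = 0,
    groups: tuple[str, str] = ("NC", "AD"),
) -> SyntheticConfig:
    """Two groups differing in stationary covariance at known effect edges."""
    base = exchangeable_correlation(n_rois)
    edges = [(i, j) for i, j in _default_effect_edges() if j < n_rois]
    effect = make_group_covariance(base, edges, delta)
    return SyntheticConfig(
        state_covariances={"base": base, "effect": effect},
        state_schedule_per_group={
            groups[0]: [("base", n_timepoints)],
            groups[1]: [("effect", n_timepoints)],
        },
        n_subjects_per_group=n_subjects_per_group,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        effect_edges=edges,
        delta=delta,
        seed=seed,
    )


def sequence_only_config(
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS,
    n_rois: int = DEFAULT_N_ROIS,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    delta: float = DEFAULT_DELTA,
    seed: int = 0,
    groups: tuple[str, str] = ("NC", "AD"),
) -> SyntheticConfig:
    """Groups share two covariance states but visit them in opposite order.

    Stationary (whole-series) statistics match across groups; only the
    window-to-window sequence carries the group difference.
    """
    base = exchangeable_correlation(n_rois)
    half = n_rois // 2
    edges_a = [(2 * i, 2 * i + 1) for i in range(min(5, half // 2))]
    edges_b = [(half + 2 * i, half + 2 * i + 1) for i in range(min(5, half // 2))]
    state_a = make_group_covariance(base, edges_a, delta)
    state_b = make_group_covariance(base, edges_b, delta)
    d1 = n_timepoints // 2
    d2 = n_timepoints - d1
    return SyntheticConfig(
        state_covariances={"A": state_a, "B": state_b},
        state_schedule_per_group={
            groups[0]: [("A", d1), ("B", d2)],
            groups[1]: [("B", d1), ("A", d2)],
        },
        n_subjects_per_group=n_subjects_per_group,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        effect_edges=edges_a + edges_b,
        delta=delta,
        seed=seed,
    )


def null_config(
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS,
    n_rois: int = DEFAULT_N_ROIS,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    seed: int = 0,
    groups: tuple[str, str] = ("NC", "AD"),
) -> SyntheticConfig:
    """Both groups identically distributed (no effect anywhere)."""
    base = exchangeable_correlation(n_rois)
    return SyntheticConfig(
        state_covariances={"base": base},
        state_schedule_per_group={
            groups[0]: [("base", n_timepoints)],
            groups[1]: [("base", n_timepoints)],
        },
        n_subjects_per_group=n_subjects_per_group,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    config: SyntheticConfig,
    group: str,
    rng: np.random.Generator,
    scan_id: str = "scan",
    n_timepoints: int | None = None,
) -> RoiTimeSeries:
    """Draw one scan: Gaussian segments following the group's state schedule,
    plus isotropic noise of sd ``noise_sd``.

    ``n_timepoints`` may override the configured length (the last schedule
    run is stretched/shrunk), used by convergence checks at large n.
    """
    schedule = list(config.state_schedule_per_group[group])
    if n_timepoints is not None and n_timepoints != config.n_timepoints:
        state, dur = schedule[-1]
        schedule[-1] = (state, dur + n_timepoints - config.n_timepoints)
        if schedule[-1][1] <= 0:
            raise ValueError("n_timepoints override too short for schedule")
    chunks = []
    for state, dur in schedule:
        L = np.linalg.cholesky(config.state_covariances[state])
        chunks.append(rng.standard_normal((dur, config.n_rois)) @ L.T)
    values = np.concatenate(chunks, axis=0)
    if config.noise_sd > 0:
        values = values + config.noise_sd * rng.standard_normal(values.shape)
    return RoiTimeSeries(scan_id=scan_id, values=values)


def simulate_cohort(config: SyntheticConfig) -> Cohort:
    """Simulate the full multi-scan cohort described by ``config``.

    Per-scan generators are derived by hashing (seed, group, subject, scan)
    through NumPy's SeedSequence, so any scan is reproducible in isolation.
    """
    records: list[ScanRecord] = []
    series: dict[str, RoiTimeSeries] = {}
    for g_idx, group in enumerate(config.groups):
        for s_idx in range(config.n_subjects_per_group):
            subj_rng = np.random.default_rng([config.seed, g_idx, s_idx])
            subject_id = f"S{group}{s_idx:03d}"
            n_scans = 1 + int(subj_rng.random() < config.multi_scan_prob)
            has_baseline = subj_rng.random() >= config.baseline_missing_prob
            for k in range(n_scans):
                scan_id = f"{subject_id}_V{k}"
                scan_rng = np.random.default_rng([config.seed, g_idx, s_idx, k])
                series[scan_id] = simulate_subject(config, group, scan_rng, scan_id=scan_id)
                records.append(
                    ScanRecord(
                        subject_id=subject_id,
                        scan_id=scan_id,
                        label=group,
                        is_baseline=has_baseline and k == 0,
                    )
                )
    return Cohort(records=records, series=series)


def ground_truth(config: SyntheticConfig) -> dict:
    """JSON-serialisable record of what was injected (for recovery tests)."""
    return {
        "effect_edges": [list(e) for e in config.effect_edges],
        "delta": config.delta,
        "schedules": {
            g: [[s, int(d)] for s, d in sched]
            for g, sched in config.state_schedule_per_group.items()
        },
        "n_subjects_per_group": config.n_subjects_per_group,
        "n_rois": config.n_rois,
        "n_timepoints": config.n_timepoints,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
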