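"""Dynamic functional-connectivity tensor construction.

A scan's ROI time series (M timepoints x N ROIs) is partitioned into T
overlapping windows of length L taken every S timepoints, and within each
window the N x N matrix of Pearson correlation coefficients between ROI
signals is computed.  Stacking the windows gives the dFC tensor
G = [G^1 ... G^T] of shape (T, N, N) that the downstream network consumes.
Windows are rectangular (no taper), 0-based and half-open; a trailing
segment that does not fill a whole window is dropped, so
T = floor((M - L) / S) + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .io_cohort import RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window length L and stride S, both in timepoints (TR units)."""

    L: int = 70
    S: int = 2

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"window length must be >= 2, got {self.L}")
        if self.S < 1:
            raise ValueError(f"stride must be >= 1, got {self.S}")


@dataclass
class DfcTensor:
    """Stack of windowed correlation matrices for one scan: shape (T, N, N)."""

    values: np.ndarray
    window_config: SlidingWindowConfig
    scan_id: str

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def num_windows(M: int, L: int, S: int) -> int:
    """Number of full windows of length L at stride S in a series of M points.

    floor((M - L) / S) + 1; e.g. M=137, L=70, S=2 gives 34 windows.
    """
    if L > M:
        raise ValueError(f"window length {L} exceeds series length {M}")
    return (M - L) // S + 1


def window_bounds(t: int, config: SlidingWindowConfig, M: int) -> tuple[int, int]:
    """Half-open timepoint interval [t*S, t*S + L) of the t-th window (0-based)."""
    T = num_windows(M, config.L, config.S)
    if not 0 <= t < T:
        raise IndexError(f"window index {t} out of range [0, {T})")
    start = t * config.S
    return start, start + config.L


def pearson_matrix(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of an L x N segment (columns = ROIs).

    Zero-variance columns cannot carry a correlation: every entry involving
    them, including the diagonal, is set to 0 and a warning is logged.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ValueError(f"segment must be 2-D with >= 2 rows, got {segment.shape}")
    n = segment.shape[1]
    sd = segment.std(axis=0)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "pearson_matrix: %d zero-variance column(s); their correlations set to 0",
            int(constant.sum()),
        )
        out = np.zeros((n, n))
        live = ~constant
        if live.sum() >= 2:
            sub = np.corrcoef(segment[:, live], rowvar=False)
            out[np.ix_(live, live)] = sub
        elif live.sum() == 1:
            out[np.argmax(live), np.argmax(live)] = 1.0
        corr = out
    else:
        corr = np.corrcoef(segment, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    return (corr + corr.T) / 2.0


def build_dfc(ts: RoiTimeSeries, config: SlidingWindowConfig) -> DfcTensor:
    """Build the (T, N, N) dFC tensor of one scan."""
    M = ts.n_timepoints
    T = num_windows(M, config.L, config.S)
    N = ts.n_rois
    values = np.empty((T, N, N))
    for t in range(T):
        a, b = window_bounds(t, config, M)
        values[t] = pearson_matrix(ts.values[a:b])
    return DfcTensor(values=values, window_config=config, scan_id=ts.scan_id)


def save_dfc(path: str | Path, dfc: DfcTensor) -> None:
    """Persist a dFC tensor to HDF5 (dataset ``dfc``, float32, attrs L/S/scan_id)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("dfc", data=dfc.values.astype(np.float32))
        ds.attrs["L"] = dfc.window_config.L
        ds.attrs["S"] = dfc.window_config.S
        ds.attrs["scan_id"] = dfc.scan_id


def load_dfc(path: str | Path) -> DfcTensor:
    with h5py.File(path, "r") as fh:
        ds = fh["dfc"]
        return DfcTensor(
            values=np.asarray(ds, dtype=float),
            window_config=SlidingWindowConfig(L=int(ds.attrs["L"]), S=int(ds.attrs["S"])),
            scan_id=str(ds.attrs["scan_id"]),
        )
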