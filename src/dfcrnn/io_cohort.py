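"""Cohort input/output: ROI time-series matrices and the phenotype table.

The pipeline consumes parcellated rs-fMRI data: for each scan, one matrix of
shape M timepoints x N regions of interest (ROIs), holding the mean BOLD
signal of every atlas region at every repetition time.  Image-space
preprocessing (motion correction, registration, parcellation) happens
upstream; this module only reads the resulting delimited-text matrices,
validates the phenotype table, and applies the initial-volume discard that
removes the scanner's non-equilibrium leading volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Diagnostic classes, in their fixed index order (NC=0, eMCI=1, lMCI=2, AD=3).
LABELS: tuple[str, ...] = ("NC", "eMCI", "lMCI", "AD")
LABEL_TO_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}

#: Default number of leading volumes discarded before any analysis.
DEFAULT_DISCARD_VOLUMES = 3


class CohortFormatError(ValueError):
    """Malformed time-series file, phenotype table, or cohort manifest."""


@dataclass
class RoiTimeSeries:
    """One scan's ROI-mean BOLD matrix: M timepoints (rows) x N ROIs (columns)."""

    scan_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortFormatError(
                f"{self.scan_id}: time series must be 2-D, got shape {self.values.shape}"
            )
        m, n = self.values.shape
        if m < 2:
            raise CohortFormatError(f"{self.scan_id}: need at least 2 timepoints, got {m}")
        if n < 2:
            raise CohortFormatError(f"{self.scan_id}: need at least 2 ROIs, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise CohortFormatError(f"{self.scan_id}: non-finite entries in time series")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScanRecord:
    """Phenotype row for one scan.

    A subject may contribute several scans acquired at different visits; all
    carry the subject's diagnostic label, and at most one is the baseline
    (enrollment) scan.
    """

    subject_id: str
    scan_id: str
    label: str
    is_baseline: bool

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise CohortFormatError(
                f"scan {self.scan_id}: unknown label {self.label!r}; "
                f"valid labels are {', '.join(LABELS)}"
            )

    @property
    def label_index(self) -> int:
        return LABEL_TO_INDEX[self.label]


@dataclass
class Cohort:
    """All scans of a study: phenotype records plus their time-series matrices."""

    records: list[ScanRecord]
    series: dict[str, RoiTimeSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_records(self.records)
        if self.series:
            rec_ids = {r.scan_id for r in self.records}
            ser_ids = set(self.series)
            if rec_ids != ser_ids:
                missing = sorted(rec_ids - ser_ids)
                extra = sorted(ser_ids - rec_ids)
                raise CohortFormatError(
                    f"records/series mismatch: missing series for {missing}, "
                    f"series without record for {extra}"
                )

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def scans_of(self, subject_id: str) -> list[ScanRecord]:
        return [r for r in self.records if r.subject_id == subject_id]

    def baseline_scan(self, subject_id: str) -> ScanRecord | None:
        for r in self.scans_of(subject_id):
            if r.is_baseline:
                return r
        return None


def validate_records(records: list[ScanRecord]) -> None:
    """Enforce cohort invariants: unique scan ids, one label and at most one
    baseline scan per subject."""
    seen_scans: set[str] = set()
    labels: dict[str, str] = {}
    baselines: dict[str, int] = {}
    for r in records:
        if r.scan_id in seen_scans:
            raise CohortFormatError(f"duplicate scan_id {r.scan_id!r}")
        seen_scans.add(r.scan_id)
        prev = labels.setdefault(r.subject_id, r.label)
        if prev != r.label:
            raise CohortFormatError(
                f"subject {r.subject_id!r} has conflicting labels {prev!r} and {r.label!r}"
            )
        if r.is_baseline:
            baselines[r.subject_id] = baselines.get(r.subject_id, 0) + 1
            if baselines[r.subject_id] > 1:
                raise CohortFormatError(
                    f"subject {r.subject_id!r} has more than one baseline scan"
                )


# ---------------------------------------------------------------------------
# Time-series files (delimited text, rows = timepoints)
# ---------------------------------------------------------------------------

def read_roi_timeseries(
    path: str | Path,
    n_rois: int,
    delimiter: str = "\t",
    scan_id: str | None = None,
) -> RoiTimeSeries:
    """Read one scan's M x N matrix from a delimited text file.

    The file must be a rectangular numeric table with exactly ``n_rois``
    columns.  Errors name the first offending line (1-based).
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(delimiter) if delimiter != " " else line.split()
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise CohortFormatError(
                    f"{path.name}: non-numeric cell on line {lineno}: {exc}"
                ) from None
            if rows and len(row) != len(rows[0]):
                raise CohortFormatError(
                    f"{path.name}: ragged row on line {lineno}: "
                    f"expected {len(rows[0])} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise CohortFormatError(f"{path.name}: empty file")
    if len(rows[0]) != n_rois:
        raise CohortFormatError(
            f"{path.name}: expected {n_rois} ROI columns, found {len(rows[0])} (line 1)"
        )
    return RoiTimeSeries(scan_id=scan_id or path.stem, values=np.asarray(rows))


def write_roi_timeseries(
    path: str | Path, ts: RoiTimeSeries, delimiter: str = "\t", fmt: str = "%.10g"
) -> None:
    np.savetxt(path, ts.values, delimiter=delimiter, fmt=fmt)


def trim_initial_volumes(ts: RoiTimeSeries, k: int) -> RoiTimeSeries:
    """Drop the first ``k`` timepoints (non-equilibrium leading volumes).

    With the common protocol of 140 acquired volumes and k=3, the remaining
    series has 137 timepoints.
    """
    if k < 0:
        raise ValueError(f"discard count must be >= 0, got {k}")
    if k == 0:
        return ts
    if k >= ts.n_timepoints:
        raise ValueError(
            f"{ts.scan_id}: cannot discard {k} of {ts.n_timepoints} timepoints"
        )
    return RoiTimeSeries(scan_id=ts.scan_id, values=ts.values[k:].copy())


# ---------------------------------------------------------------------------
# Phenotype table (CSV) and cohort manifest (JSON)
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = ["subject_id", "scan_id", "label", "is_baseline"]


def read_phenotype_table(path: str | Path) -> list[ScanRecord]:
    """Read and validate the phenotype CSV (columns: subject_id, scan_id,
    label, is_baseline)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "scan_id": str, "label": str})
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"phenotype table missing columns: {missing}")
    records = [
        ScanRecord(
            subject_id=row.subject_id,
            scan_id=row.scan_id,
            label=row.label,
            is_baseline=_parse_bool(row.is_baseline),
        )
        for row in df.itertuples()
    ]
    validate_records(records)
    return records


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise CohortFormatError(f"cannot parse boolean value {x!r} in is_baseline")


def write_phenotype_table(path: str | Path, records: list[ScanRecord]) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "scan_id": r.scan_id,
                "label": r.label,
                "is_baseline": r.is_baseline,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_cohort(cohort: Cohort, out_dir: str | Path, delimiter: str = "\t") -> Path:
    """Write a cohort to disk in the standard layout and return the manifest path.

    Layout: ``phenotype.csv``, ``series/<scan_id>.tsv`` (one file per scan),
    and ``manifest.json`` listing both.
    """
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)
    write_phenotype_table(out_dir / "phenotype.csv", cohort.records)
    for scan_id, ts in cohort.series.items():
        write_roi_timeseries(series_dir / f"{scan_id}.tsv", ts, delimiter=delimiter)
    n_rois = next(iter(cohort.series.values())).n_rois if cohort.series else 0
    manifest = {
        "phenotype": "phenotype.csv",
        "series_dir": "series",
        "delimiter": delimiter,
        "n_rois": n_rois,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(
    manifest_path: str | Path,
    discard_volumes: int = DEFAULT_DISCARD_VOLUMES,
    n_rois: int | None = None,
) -> Cohort:
    """Load a cohort from its manifest, trimming ``discard_volumes`` leading
    timepoints from every scan (pass 0 for already-trimmed inputs)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    records = read_phenotype_table(root / manifest["phenotype"])
    delimiter = manifest.get("delimiter", "\t")
    if n_rois is None:
        n_rois = int(manifest["n_rois"])
    series: dict[str, RoiTimeSeries] = {}
    for r in records:
        ts = read_roi_timeseries(
            root / manifest["series_dir"] / f"{r.scan_id}.tsv",
            n_rois=n_rois,
            delimiter=delimiter,
            scan_id=r.scan_id,
        )
        series[r.scan_id] = trim_initial_volumes(ts, discard_volumes)
    return Cohort(records=records, series=series)


def trim_cohort(cohort: Cohort, k: int) -> Cohort:
    """Return a copy of an in-memory cohort with k leading volumes discarded."""
    return Cohort(
        records=list(cohort.records),
        series={sid: trim_initial_volumes(ts, k) for sid, ts in cohort.series.items()},
    )
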