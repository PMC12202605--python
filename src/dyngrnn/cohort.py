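"""Reading/writing ROI time-series files and cohort manifests, and subject-level splits.

An ROI time-series file is a delimited numeric table holding one subject's
parcellated BOLD matrix. On disk the default orientation is ``time_by_roi``
(rows = scan volumes, columns = regions, optionally headed by a row of ROI
labels); in memory the canonical layout is always ROI x time.

A cohort manifest is a delimited table with columns ``subject_id``, ``group``,
``path`` plus free covariate columns (age, sex, MMSE, ...). Splitting into
train/validation/test operates on subjects, never on individual scans, so no
subject's windows can leak across splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dyngrnn.exceptions import ConfigError, DimensionError, FormatError, ParseError

__all__ = [
    "ROITimeSeries",
    "SubjectRecord",
    "CohortManifest",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_manifest",
    "write_manifest",
    "split_cohort",
]

_ORIENTATIONS = ("time_by_roi", "roi_by_time")


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's parcellated BOLD matrix, ROI x time, with ROI labels."""

    subject_id: str
    roi_labels: tuple[str, ...]
    data: np.ndarray  # shape (n_rois, n_timepoints), float64
    sampling_interval: float | None = None  # seconds, if known

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if data.ndim != 2:
            raise DimensionError(f"data must be 2-D, got shape {data.shape}")
        n, t = data.shape
        if n < 2 or t < 2:
            raise DimensionError(f"need >=2 ROIs and >=2 timepoints, got {n}x{t}")
        if not np.all(np.isfinite(data)):
            raise DimensionError("time series contains non-finite values")
        if len(self.roi_labels) != n:
            raise DimensionError(
                f"{len(self.roi_labels)} labels for {n} ROIs"
            )
        if len(set(self.roi_labels)) != n:
            raise DimensionError("ROI labels must be unique")
        if self.sampling_interval is not None and self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    path: str | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortManifest:
    """An ordered collection of subjects with a declared label set."""

    records: tuple[SubjectRecord, ...]
    label_set: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "label_set", tuple(self.label_set))
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate subject_id in manifest")
        labels = set(self.label_set)
        for r in self.records:
            if r.group not in labels:
                raise ConfigError(
                    f"subject {r.subject_id}: group {r.group!r} not in label set {self.label_set}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in self.label_set}
        for r in self.records:
            counts[r.group] += 1
        return counts


def default_roi_labels(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"ROI_{i + 1:0{width}d}" for i in range(n))


def _parse_table(path: Path, delimiter: str) -> tuple[list[str] | None, np.ndarray]:
    """Parse a delimited numeric table, returning (header labels or None, values).

    Header detection: if any token of the first row fails float conversion the
    row is treated as a label header. Parse errors in the data region report
    1-based (row, col) positions within that region.
    """
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    rows = [ln.split(delimiter) for ln in lines]

    def _all_numeric(tokens):
        try:
            [float(t) for t in tokens]
            return True
        except ValueError:
            return False

    header = None
    if not _all_numeric(rows[0]):
        header = [t.strip() for t in rows[0]]
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0])
    values = np.empty((len(rows), width), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged table, row {i + 1} has {len(row)} fields, expected {width}"
            )
        for j, tok in enumerate(row):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ParseError(i + 1, j + 1, tok) from None
    if header is not None and len(header) != width:
        raise FormatError(f"{path}: header has {len(header)} fields, table has {width}")
    return header, values


def read_roi_timeseries(
    path: str | Path,
    orientation: str = "time_by_roi",
    delimiter: str = "\t",
    subject_id: str | None = None,
) -> ROITimeSeries:
    """Read one subject's ROI time-series table.

    ``time_by_roi`` files may carry a single header row of ROI labels;
    ``roi_by_time`` files may carry a leading label column. Without labels,
    names ``ROI_001..ROI_n`` are synthesized. The returned matrix is always
    ROI x time regardless of the file orientation.
    """
    if orientation not in _ORIENTATIONS:
        raise ConfigError(f"orientation must be one of {_ORIENTATIONS}")
    path = Path(path)
    if orientation == "time_by_roi":
        header, values = _parse_table(path, delimiter)
        data = values.T
        labels = tuple(header) if header else default_roi_labels(data.shape[0])
    else:
        labels, data = _parse_labeled_rows(path, delimiter)
    if subject_id is None:
        subject_id = path.stem
    return ROITimeSeries(subject_id=subject_id, roi_labels=labels, data=data)


def _parse_labeled_rows(path: Path, delimiter: str) -> tuple[tuple[str, ...], np.ndarray]:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    rows = [ln.split(delimiter) for ln in lines]
    first = rows[0][0]
    labeled = False
    try:
        float(first)
    except ValueError:
        labeled = True
    labels: list[str] = []
    width = len(rows[0])
    values = np.empty((len(rows), width - (1 if labeled else 0)), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged table, row {i + 1} has {len(row)} fields, expected {width}"
            )
        body = row[1:] if labeled else row
        if labeled:
            labels.append(row[0].strip())
        for j, tok in enumerate(body):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ParseError(i + 1, j + 1 + (1 if labeled else 0), tok) from None
    lab = tuple(labels) if labeled else default_roi_labels(values.shape[0])
    return lab, values


def write_roi_timeseries(
    ts: ROITimeSeries,
    path: str | Path,
    orientation: str = "time_by_roi",
    delimiter: str = "\t",
) -> Path:
    """Write a time series; ``read_roi_timeseries`` on the result reproduces it."""
    if orientation not in _ORIENTATIONS:
        raise ConfigError(f"orientation must be one of {_ORIENTATIONS}")
    path = Path(path)
    fmt = "%.17g"
    with path.open("w") as fh:
        if orientation == "time_by_roi":
            fh.write(delimiter.join(ts.roi_labels) + "\n")
            for row in ts.data.T:
                fh.write(delimiter.join(fmt % v for v in row) + "\n")
        else:
            for label, row in zip(ts.roi_labels, ts.data):
                fh.write(label + delimiter + delimiter.join(fmt % v for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# manifests

_RESERVED = ("subject_id", "group", "path")


def read_manifest(path: str | Path, delimiter: str = "\t") -> CohortManifest:
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str, "group": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"manifest missing required column {col!r}")
    cov_cols = [c for c in df.columns if c not in _RESERVED]
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                path=str(row["path"]) if "path" in df.columns else None,
                covariates={c: row[c] for c in cov_cols},
            )
        )
    label_set = tuple(dict.fromkeys(r.group for r in records))
    return CohortManifest(records=tuple(records), label_set=label_set)


def write_manifest(manifest: CohortManifest, path: str | Path, delimiter: str = "\t") -> Path:
    path = Path(path)
    cov_cols: list[str] = []
    for r in manifest.records:
        for c in r.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    rows = []
    for r in manifest.records:
        row = {"subject_id": r.subject_id, "group": r.group, "path": r.path or ""}
        row.update({c: r.covariates.get(c, "") for c in cov_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    return path


# ---------------------------------------------------------------------------
# splitting

def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion n items to len(ratios) bins; ties go to earlier bins."""
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    # stable sort on descending fractional part keeps bin order for ties
    order = sorted(range(len(ratios)), key=lambda i: -(exact[i] - base[i]))
    for i in order[:short]:
        base[i] += 1
    return base


def split_cohort(
    manifest: CohortManifest,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratify: bool = True,
) -> tuple[CohortManifest, CohortManifest, CohortManifest]:
    """Split subjects into train/validation/test manifests.

    Sizes follow largest-remainder rounding of ``ratios`` (ties broken in
    train > val > test order); with ``stratify`` the rounding is applied within
    each diagnostic group. Deterministic for a given seed.
    """
    if len(manifest) == 0:
        raise ConfigError("cannot split an empty manifest")
    ratios = [float(r) for r in ratios]
    if len(ratios) != 3:
        raise ConfigError("ratios must have exactly three entries")
    if any(r < 0 for r in ratios):
        raise ConfigError("ratios must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must sum to 1, got {sum(ratios)}")

    rng = np.random.default_rng(seed)
    n_splits = sum(1 for r in ratios if r > 0)
    buckets: list[list[SubjectRecord]] = [[], [], []]

    def _assign(records: list[SubjectRecord]):
        idx = rng.permutation(len(records))
        sizes = _largest_remainder(len(records), ratios)
        pos = 0
        for b, size in enumerate(sizes):
            for i in idx[pos:pos + size]:
                buckets[b].append(records[i])
            pos += size

    if stratify:
        leftovers: list[SubjectRecord] = []
        for g in manifest.label_set:
            group_records = [r for r in manifest.records if r.group == g]
            if not group_records:
                continue
            if len(group_records) < n_splits:
                warnings.warn(
                    f"group {g!r} has {len(group_records)} subjects, fewer than "
                    f"{n_splits} splits; assigned by global rounding",
                    stacklevel=2,
                )
                leftovers.extend(group_records)
            else:
                _assign(group_records)
        if leftovers:
            _assign(leftovers)
    else:
        _assign(list(manifest.records))

    order = {r.subject_id: i for i, r in enumerate(manifest.records)}
    out = []
    for bucket in buckets:
        bucket.sort(key=lambda r: order[r.subject_id])
        out.append(CohortManifest(records=tuple(bucket), label_set=manifest.label_set))
    return out[0], out[1], out[2]
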