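"""Synthetic ROI time-series cohorts with known correlation structure.

The generator draws each subject's BOLD matrix from a zero-mean multivariate
normal whose correlation matrix encodes (a) a block/community structure shared
by all subjects, (b) an optional alternation between two covariance states
over time (the "dynamic" regime a sliding-window pipeline should resolve and a
whole-series correlation should blur), and (c) class-dependent connectivity
deltas on designated ROI pairs (the ground-truth biomarkers). Independent
Gaussian observation noise can be added on top.

When a state schedule is present the class deltas act in the second state
only, so an affected pair alternates between its baseline and shifted
correlation: a genuinely dynamic, class-specific connectivity signature.
Without a schedule the deltas act unconditionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from dyngrnn.cohort import (
    CohortManifest,
    ROITimeSeries,
    SubjectRecord,
    default_roi_labels,
    write_manifest,
    write_roi_timeseries,
)
from dyngrnn.exceptions import SpecError

__all__ = [
    "BlockStructure",
    "SyntheticSpec",
    "build_covariance",
    "nearest_correlation",
    "generate_subject",
    "generate_cohort",
    "generate_cohort_arrays",
]

_MIN_EIG = 1e-8


@dataclass(frozen=True)
class BlockStructure:
    """Partition of ROIs into communities with base correlations.

    ``within`` is the within-community correlation in the first covariance
    state; ``within_state2`` (if set) replaces it in the second state, making
    community coupling itself time-varying. ``between`` applies across
    communities in both states.
    """

    blocks: tuple[tuple[int, ...], ...]
    within: float = 0.3
    between: float = 0.0
    within_state2: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        for v in (self.within, self.between, self.within_state2):
            if v is not None and not -1 < v < 1:
                raise SpecError(f"base correlation {v} outside (-1, 1)")

    @staticmethod
    def even(n_rois: int, n_blocks: int, within: float = 0.3, between: float = 0.0,
             within_state2: float | None = None) -> "BlockStructure":
        """Split ``n_rois`` into ``n_blocks`` near-equal contiguous communities."""
        bounds = np.linspace(0, n_rois, n_blocks + 1).astype(int)
        blocks = tuple(tuple(range(bounds[i], bounds[i + 1])) for i in range(n_blocks))
        return BlockStructure(blocks, within, between, within_state2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    class_effects maps a group label to (roi_i, roi_j, delta) triples added to
    the baseline correlation of that pair (second state only when
    ``state_period`` is set). ``state_period`` is the number of timepoints
    spent in each covariance state before switching.
    """

    n_rois: int = 90
    n_timepoints: int = 198
    n_subjects_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 33, "EMCI": 29, "AD": 23}
    )
    block_structure: BlockStructure | None = None
    state_period: int | None = None
    class_effects: Mapping[str, Sequence[tuple[int, int, float]]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rois < 2 or self.n_timepoints < 2:
            raise SpecError("need n_rois >= 2 and n_timepoints >= 2")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        if self.state_period is not None and self.state_period < 1:
            raise SpecError("state_period must be a positive number of timepoints")
        bs = self.block_structure
        if bs is None:
            bs = BlockStructure.even(self.n_rois, 1, within=0.0)
            object.__setattr__(self, "block_structure", bs)
        seen: set[int] = set()
        for block in bs.blocks:
            for i in block:
                if i in seen or not 0 <= i < self.n_rois:
                    raise SpecError("block_structure is not a partition of the ROIs")
                seen.add(i)
        if len(seen) != self.n_rois:
            raise SpecError("block_structure does not cover every ROI")
        for label, effects in self.class_effects.items():
            for i, j, _ in effects:
                if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                    raise SpecError(f"invalid effect pair ({i},{j}) for class {label!r}")
        # fail fast if any implied per-state matrix cannot be made a correlation
        for label in self.labels:
            for state in self.n_states_range:
                build_covariance(self, label, state)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.n_subjects_per_class)

    @property
    def n_states(self) -> int:
        return 2 if self.state_period is not None else 1

    @property
    def n_states_range(self) -> range:
        return range(self.n_states)


def nearest_correlation(matrix: np.ndarray, min_eig: float = _MIN_EIG) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest positive-definite correlation.

    Clips eigenvalues at ``min_eig`` and re-normalizes to unit diagonal.
    """
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.maximum(vals, min_eig)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def build_covariance(spec: SyntheticSpec, label: str, state_index: int = 0) -> np.ndarray:
    """Correlation matrix for one class in one covariance state.

    Symmetric with unit diagonal and positive definite; a spec whose block/
    delta combination is indefinite is repaired by eigenvalue clipping (with a
    warning) or rejected if the repair moves any specified entry out of range.
    """
    n = spec.n_rois
    bs = spec.block_structure
    corr = np.full((n, n), bs.between, dtype=float)
    within = bs.within
    if state_index == 1 and bs.within_state2 is not None:
        within = bs.within_state2
    for block in bs.blocks:
        idx = np.asarray(block, dtype=int)
        corr[np.ix_(idx, idx)] = within
    np.fill_diagonal(corr, 1.0)
    apply_effects = spec.state_period is None or state_index == 1
    if apply_effects:
        for i, j, delta in spec.class_effects.get(label, ()):
            value = corr[i, j] + delta
            if not -1 < value < 1:
                raise SpecError(
                    f"class {label!r}: correlation {value:.3f} on pair ({i},{j}) outside (-1,1)"
                )
            corr[i, j] = corr[j, i] = value
    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig <= _MIN_EIG:
        warnings.warn(
            f"correlation matrix for class {label!r} state {state_index} not positive "
            f"definite (min eigenvalue {min_eig:.3e}); applying eigenvalue-clipping repair",
            stacklevel=2,
        )
        corr = nearest_correlation(corr)
        if float(np.linalg.eigvalsh(corr).min()) <= 0:
            raise SpecError("positive-definite repair failed")
    return corr


def _subject_rng(spec_seed: int, subject_seed: int) -> np.random.Generator:
    # SeedSequence decouples subjects: adding subjects never perturbs earlier draws
    return np.random.default_rng(np.random.SeedSequence((spec_seed, subject_seed)))


def _state_sequence(n_timepoints: int, period: int | None) -> np.ndarray:
    if period is None:
        return np.zeros(n_timepoints, dtype=int)
    return (np.arange(n_timepoints) // period) % 2


def generate_subject(spec: SyntheticSpec, label: str, subject_seed: int,
                     subject_id: str | None = None) -> ROITimeSeries:
    """Draw one subject's ROI x time matrix; deterministic in (spec.seed, subject_seed)."""
    rng = _subject_rng(spec.seed, subject_seed)
    chol = [np.linalg.cholesky(build_covariance(spec, label, s)) for s in spec.n_states_range]
    states = _state_sequence(spec.n_timepoints, spec.state_period)
    z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
    data = np.empty((spec.n_timepoints, spec.n_rois))
    for s in spec.n_states_range:
        mask = states == s
        data[mask] = z[mask] @ chol[s].T
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    if subject_id is None:
        subject_id = f"{label}_{subject_seed:04d}"
    return ROITimeSeries(
        subject_id=subject_id,
        roi_labels=default_roi_labels(spec.n_rois),
        data=data.T,
    )


def generate_cohort_arrays(spec: SyntheticSpec) -> list[tuple[ROITimeSeries, str]]:
    """Generate the whole cohort in memory as (time series, group label) pairs."""
    out = []
    counter = 0
    for label, count in spec.n_subjects_per_class.items():
        for _ in range(count):
            ts = generate_subject(spec, label, subject_seed=counter,
                                  subject_id=f"{label}_{counter:04d}")
            out.append((ts, label))
            counter += 1
    return out


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path) -> CohortManifest:
    """Write one time-series file per subject plus a manifest and ground-truth
    effects table (``effects.tsv``: label, roi_i, roi_j, delta) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for ts, label in generate_cohort_arrays(spec):
        path = out_dir / f"{ts.subject_id}.tsv"
        write_roi_timeseries(ts, path)
        records.append(SubjectRecord(subject_id=ts.subject_id, group=label, path=str(path)))
    manifest = CohortManifest(records=tuple(records), label_set=spec.labels)
    write_manifest(manifest, out_dir / "manifest.tsv")
    with (out_dir / "effects.tsv").open("w") as fh:
        fh.write("label\troi_i\troi_j\tdelta\n")
        for label, effects in spec.class_effects.items():
            for i, j, delta in effects:
                fh.write(f"{label}\t{i}\t{j}\t{delta}\n")
    return manifest
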