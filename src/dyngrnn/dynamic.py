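"""Dynamic functional graph construction from one subject's ROI time series.

A series of length K is cut into m = floor((K - w)/s) + 1 half-open windows
[i*s, i*s + w); trailing samples that do not fill a window are dropped. Node
features are the per-window means of each ROI's signal (slide piecewise
aggregation); edge features are the per-window Pearson correlations between
ROI pairs, subsequently min-max normalized to [0, 1] along each pair's own
window axis so every edge trajectory spans the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dyngrnn.cohort import ROITimeSeries
from dyngrnn.exceptions import ConfigError, DimensionError

__all__ = [
    "SlidingWindowConfig",
    "DynamicGraph",
    "count_windows",
    "window_starts",
    "spa_node_features",
    "windowed_pcc",
    "minmax_normalize_edges",
    "build_dynamic_graph",
]


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window width and step, both in timepoints (samples)."""

    width: int = 30
    step: int = 4

    def __post_init__(self):
        if self.width < 1:
            raise ConfigError("window width must be >= 1")
        if self.step < 1:
            raise ConfigError("window step must be >= 1")


@dataclass(frozen=True)
class DynamicGraph:
    """Per-window node features and (raw + normalized) edge features.

    node_features[i, k] is ROI i's mean signal in window k; edge_features_raw
    holds windowed Pearson correlations in [-1, 1] with unit diagonal;
    edge_features holds the per-pair min-max normalized values in [0, 1].
    Self-loops are excluded from any adjacency derived downstream.
    """

    roi_labels: tuple[str, ...]
    window_starts: np.ndarray  # (m,) 0-based start offsets
    node_features: np.ndarray  # (n, m)
    edge_features_raw: np.ndarray  # (n, n, m)
    edge_features: np.ndarray  # (n, n, m)

    @property
    def n_rois(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_windows(self) -> int:
        return self.node_features.shape[1]

    def mean_adjacency(self) -> np.ndarray:
        """Window-averaged normalized adjacency with zeroed diagonal."""
        adj = self.edge_features.mean(axis=2)
        np.fill_diagonal(adj, 0.0)
        return adj


def count_windows(n_timepoints: int, width: int, step: int) -> int:
    """Number of full windows of ``width`` advancing by ``step`` over the series."""
    if width < 1 or step < 1:
        raise ConfigError("width and step must be >= 1")
    if width > n_timepoints:
        raise DimensionError(
            f"window width {width} exceeds series length {n_timepoints}"
        )
    return (n_timepoints - width) // step + 1


def window_starts(n_timepoints: int, width: int, step: int) -> np.ndarray:
    m = count_windows(n_timepoints, width, step)
    return np.arange(m) * step


def spa_node_features(ts: ROITimeSeries, cfg: SlidingWindowConfig) -> np.ndarray:
    """Per-window mean signal for every ROI: the (n, m) node-feature matrix."""
    starts = window_starts(ts.n_timepoints, cfg.width, cfg.step)
    out = np.empty((ts.n_rois, len(starts)))
    for k, t in enumerate(starts):
        out[:, k] = ts.data[:, t:t + cfg.width].mean(axis=1)
    return out


def windowed_pcc(ts: ROITimeSeries, cfg: SlidingWindowConfig) -> np.ndarray:
    """Windowed Pearson correlations, shape (n, n, m).

    Symmetric per window with unit diagonal. A signal that is constant within
    a window yields correlation 0 against every other ROI (no evidence of
    linear association, kept finite for downstream arithmetic).
    """
    if cfg.width < 2:
        raise ConfigError("windowed correlation requires width >= 2")
    starts = window_starts(ts.n_timepoints, cfg.width, cfg.step)
    n = ts.n_rois
    out = np.empty((n, n, len(starts)))
    for k, t in enumerate(starts):
        seg = ts.data[:, t:t + cfg.width]
        centered = seg - seg.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered ** 2).sum(axis=1))
        cov = centered @ centered.T
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(norms, norms)
        corr[~np.isfinite(corr)] = 0.0
        corr = np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        out[:, :, k] = corr
    return out


def minmax_normalize_edges(raw: np.ndarray) -> np.ndarray:
    """Rescale each pair's window trajectory to [0, 1] by its own min and max.

    A constant trajectory (max == min) maps to 0.5 everywhere: neutral
    mid-scale rather than branding a constantly strong edge as 0.
    """
    raw = np.asarray(raw, dtype=float)
    lo = raw.min(axis=2, keepdims=True)
    hi = raw.max(axis=2, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (raw - lo) / span
    out = np.where(span > 0, out, 0.5)
    return np.clip(out, 0.0, 1.0)


def build_dynamic_graph(ts: ROITimeSeries, cfg: SlidingWindowConfig) -> DynamicGraph:
    """Compose windowing, piecewise-mean node features and normalized PCC edges."""
    starts = window_starts(ts.n_timepoints, cfg.width, cfg.step)
    raw = windowed_pcc(ts, cfg)
    return DynamicGraph(
        roi_labels=ts.roi_labels,
        window_starts=starts,
        node_features=spa_node_features(ts, cfg),
        edge_features_raw=raw,
        edge_features=minmax_normalize_edges(raw),
    )
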