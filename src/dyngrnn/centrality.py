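"""Graph-theoretic core-node identification.

Three hub measures on an unweighted brain graph — degree (edge count),
betweenness (fraction of shortest paths through a node, normalized over
ordered pairs by 1/((N-1)(N-2))) and closeness (reciprocal of summed hop
distances) — are combined into a slope-weighted composite score. A node
counts as a core node for a metric when its value strictly exceeds the mean
plus the population variance of that metric over all nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from dyngrnn.exceptions import ConfigError, DimensionError

__all__ = [
    "BinaryGraph",
    "CoreNodeSummary",
    "CentralityReport",
    "binarize",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "normalize_metric",
    "slope_weights",
    "composite_count",
    "core_threshold",
    "core_nodes",
    "centrality_report",
]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted graph as a symmetric 0/1 adjacency, no self-loops."""

    adjacency: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise DimensionError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise DimensionError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise DimensionError("adjacency must have a zero diagonal")
        if not np.isin(adj, (0, 1)).all():
            raise DimensionError("adjacency must be 0/1")
        object.__setattr__(self, "adjacency", adj.astype(np.int64))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != adj.shape[0]:
                raise DimensionError("label count does not match node count")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return g


def binarize(weighted: np.ndarray, mode: str = "threshold", value: float = 0.0,
             labels: Sequence[str] | None = None) -> BinaryGraph:
    """Binarize a symmetric weighted adjacency.

    ``threshold`` keeps edges with weight strictly greater than ``value``;
    ``density`` keeps the top ``value`` fraction of off-diagonal pair weights
    (ties broken by (i, j) lexical order), symmetrized.
    """
    w = np.asarray(weighted, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionError("weighted adjacency must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise DimensionError("weighted adjacency must be symmetric")
    n = w.shape[0]
    adj = np.zeros((n, n), dtype=np.int64)
    if mode == "threshold":
        mask = w > value
        np.fill_diagonal(mask, False)
        adj[mask] = 1
        adj = np.maximum(adj, adj.T)
    elif mode == "density":
        if not 0 < value <= 1:
            raise ConfigError("density must lie in (0, 1]")
        iu, ju = np.triu_indices(n, k=1)
        keep = int(round(value * len(iu)))
        # stable sort on descending weight preserves (i, j) order among ties
        order = np.argsort(-w[iu, ju], kind="stable")[:keep]
        adj[iu[order], ju[order]] = 1
        adj = np.maximum(adj, adj.T)
    else:
        raise ConfigError(f"unknown binarize mode {mode!r}")
    return BinaryGraph(adjacency=adj, labels=tuple(labels) if labels is not None else None)


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Edge count per node."""
    return g.adjacency.sum(axis=1).astype(float)


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Fraction of shortest paths through each node.

    Ordered source/target pairs (h, j), h != j, both != i, normalized by
    (N-1)(N-2); pairs with no connecting path contribute 0.
    """
    if g.n < 3:
        warnings.warn("betweenness undefined for fewer than 3 nodes; returning zeros",
                      stacklevel=2)
        return np.zeros(g.n)
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=True)
    return np.array([bc[i] for i in range(g.n)])


def closeness_centrality(g: BinaryGraph, variant: str = "raw") -> np.ndarray:
    """Closeness per node from hop-count shortest distances.

    ``raw``: 1 / sum_j D_ij. ``normalized``: (N-1) / sum_j D_ij. A node that
    cannot reach every other node gets 0 (the 1/infinity convention).
    """
    if variant not in ("raw", "normalized"):
        raise ConfigError("variant must be 'raw' or 'normalized'")
    n = g.n
    dist = shortest_path(g.adjacency, method="D", unweighted=True)
    out = np.zeros(n)
    for i in range(n):
        d = np.delete(dist[i], i)
        if np.all(np.isfinite(d)) and d.sum() > 0:
            out[i] = 1.0 / d.sum()
            if variant == "normalized":
                out[i] *= n - 1
    return out


def normalize_metric(values: np.ndarray) -> np.ndarray:
    """Min-max scale a metric vector to [0, 1]; a constant vector maps to 0."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _curve_slope(values: np.ndarray, normalize: bool) -> float:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2 or values.max() == values.min():
        return 0.0
    v = normalize_metric(values) if normalize else values
    curve = np.sort(v)[::-1]
    return abs(curve[-1] - curve[0]) / (n - 1)


def slope_weights(degree: np.ndarray, betweenness: np.ndarray, closeness: np.ndarray,
                  normalize: bool = True) -> tuple[float, float, float]:
    """Composite weights k1, k2, k3: |mean slope| of each metric's sorted
    importance curve, taken on min-max scaled values by default so the three
    weights are commensurate (``normalize=False`` uses the raw curves)."""
    return (
        _curve_slope(degree, normalize),
        _curve_slope(betweenness, normalize),
        _curve_slope(closeness, normalize),
    )


def composite_count(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                    k1: float, k2: float, k3: float) -> np.ndarray:
    """Count_i = k1*P1_i + k2*P2_i + k3*P3_i on normalized metric vectors."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    if not (p1.shape == p2.shape == p3.shape):
        raise DimensionError("P vectors must share one length")
    return k1 * p1 + k2 * p2 + k3 * p3


def core_threshold(mean: float, variance: float) -> float:
    """Core-node cut-off for a metric: mean plus (population) variance."""
    return mean + variance


@dataclass(frozen=True)
class CoreNodeSummary:
    mean: float
    variance: float
    threshold: float
    core: tuple[int, ...]  # node indices whose value strictly exceeds the threshold


def core_nodes(values: np.ndarray) -> CoreNodeSummary:
    """Mean, population variance, threshold and the strict-exceedance core set."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    variance = float(values.var())  # population (divide-by-n) variance
    thr = core_threshold(mean, variance)
    core = tuple(int(i) for i in np.flatnonzero(values > thr))
    return CoreNodeSummary(mean=mean, variance=variance, threshold=thr, core=core)


@dataclass(frozen=True)
class CentralityReport:
    labels: tuple[str, ...]
    degree: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    weights: tuple[float, float, float]
    count: np.ndarray
    summaries: dict  # metric name -> CoreNodeSummary

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "node": self.labels,
            "degree": self.degree,
            "betweenness": self.betweenness,
            "closeness": self.closeness,
            "P1": self.p1,
            "P2": self.p2,
            "P3": self.p3,
            "count": self.count,
        })
        for name, summary in self.summaries.items():
            df[f"core_{name}"] = [int(i in summary.core) for i in range(len(self.labels))]
        return df


def centrality_report(g: BinaryGraph, closeness_variant: str = "raw",
                      normalize_slopes: bool = True) -> CentralityReport:
    """All three centralities, composite score, and per-metric core-node sets."""
    deg = degree_centrality(g)
    btw = betweenness_centrality(g)
    clo = closeness_centrality(g, variant=closeness_variant)
    p1, p2, p3 = normalize_metric(deg), normalize_metric(btw), normalize_metric(clo)
    k1, k2, k3 = slope_weights(deg, btw, clo, normalize=normalize_slopes)
    count = composite_count(p1, p2, p3, k1, k2, k3)
    labels = g.labels if g.labels is not None else tuple(str(i) for i in range(g.n))
    summaries = {
        "degree": core_nodes(deg),
        "betweenness": core_nodes(btw),
        "closeness": core_nodes(clo),
        "count": core_nodes(count),
    }
    return CentralityReport(
        labels=labels, degree=deg, betweenness=btw, closeness=clo,
        p1=p1, p2=p2, p3=p3, weights=(k1, k2, k3), count=count, summaries=summaries,
    )
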