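"""Training loop, evaluation metrics, sweeps and biomarker frequency ranking.

Subjects are the sampling unit throughout: splits, batches and metrics all
operate per subject, so windows from one subject never straddle the
train/test boundary. Binary metrics follow the usual confusion-table
definitions with class index 1 as the positive class; AUC is the midrank
Mann-Whitney statistic (exactly the area under the empirical ROC curve).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from dyngrnn.cohort import CohortManifest, ROITimeSeries, read_roi_timeseries
from dyngrnn.dynamic import SlidingWindowConfig, build_dynamic_graph
from dyngrnn.exceptions import ConfigError, DimensionError
from dyngrnn.nn.model import DynamicGRNN, ModelConfig
from dyngrnn.nn.optim import Adam

__all__ = [
    "TrainConfig",
    "EvalMetrics",
    "EarlyStopper",
    "confusion_counts",
    "auc_score",
    "compute_metrics",
    "prepare_dataset",
    "train",
    "evaluate",
    "biomarker_frequency",
    "leave_one_out",
    "sweep_window",
    "sweep_pooling_ratio",
    "run_split_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; ``augment_sd`` is the standard deviation of the
    fresh Gaussian noise added to node features each time a batch is drawn
    (subject-identity noise that discourages memorizing individual feature
    patterns; 0 disables it)."""

    batch_size: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 50
    tol: float = 1e-4
    augment_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs, self.patience) < 1:
            raise ConfigError("batch_size, max_epochs and patience must be positive")
        if self.augment_sd < 0:
            raise ConfigError("augment_sd must be non-negative")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ConfigError("patience cannot exceed max_epochs")


# ---------------------------------------------------------------------------
# metrics

def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) with label 1 as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DimensionError("y_true and y_pred must have equal length")
    for arr in (y_true, y_pred):
        if not np.isin(arr, (0, 1)).all():
            raise ConfigError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fn, fp, tn


def auc_score(y_true: Sequence[int], scores: Sequence[float]) -> float | None:
    """Area under the ROC curve via the midrank Mann-Whitney statistic.

    Returns None when only one class is present (AUC undefined).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    recall: float
    precision: float
    f1: float
    auc: float | None
    degenerate: tuple[str, ...] = ()  # metrics forced to 0 by a 0/0 case

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def compute_metrics(counts: tuple[int, int, int, int],
                    scores: Sequence[float] | None = None,
                    y_true: Sequence[int] | None = None) -> EvalMetrics:
    """Accuracy/recall/precision/F1 from a confusion table, plus AUC if scores
    are given. Zero-denominator metrics are reported as 0 and flagged."""
    tp, fn, fp, tn = counts
    total = tp + fn + fp + tn
    if total == 0:
        raise ConfigError("empty evaluation")
    degenerate: list[str] = []

    def _ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / total
    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    auc = None
    if scores is not None:
        if y_true is None:
            raise ConfigError("AUC needs y_true alongside scores")
        auc = auc_score(y_true, scores)
        if auc is None:
            degenerate.append("auc")
    return EvalMetrics(tp=tp, fn=fn, fp=fp, tn=tn, accuracy=accuracy, recall=recall,
                       precision=precision, f1=f1, auc=auc,
                       degenerate=tuple(degenerate))


# ---------------------------------------------------------------------------
# data assembly

def prepare_dataset(
    subjects: Sequence[tuple[ROITimeSeries, str]] | CohortManifest,
    window: SlidingWindowConfig,
    label_set: Sequence[str] | None = None,
    standardize: bool = True,
) -> dict:
    """Build stacked model inputs from (time series, group) pairs or a manifest.

    Returns X (B, n, m) node features, E (B, n, n, m) normalized edges,
    A (B, n, n) window-averaged adjacency, integer labels y (class index in
    ``label_set`` order; index 1 is the positive class downstream).

    With ``standardize`` each ROI's window-mean trajectory is z-scored within
    the subject (the usual BOLD normalization), which puts node features on
    unit scale for the model; the raw piecewise means are kept otherwise.
    """
    if isinstance(subjects, CohortManifest):
        if label_set is None:
            label_set = subjects.label_set
        pairs = [(read_roi_timeseries(r.path, subject_id=r.subject_id), r.group)
                 for r in subjects.records]
    else:
        pairs = list(subjects)
        if label_set is None:
            label_set = tuple(dict.fromkeys(lbl for _, lbl in pairs))
    class_of = {lbl: i for i, lbl in enumerate(label_set)}
    X, E, A, y, ids = [], [], [], [], []
    roi_labels = None
    for ts, lbl in pairs:
        g = build_dynamic_graph(ts, window)
        feats = g.node_features
        if standardize:
            mu = feats.mean(axis=1, keepdims=True)
            sd = feats.std(axis=1, keepdims=True)
            feats = (feats - mu) / np.where(sd > 0, sd, 1.0)
        X.append(feats)
        E.append(g.edge_features)
        A.append(g.mean_adjacency())
        y.append(class_of[lbl])
        ids.append(ts.subject_id)
        roi_labels = g.roi_labels
    return {
        "X": np.stack(X), "E": np.stack(E), "A": np.stack(A),
        "y": np.asarray(y, dtype=int), "subject_ids": ids,
        "roi_labels": roi_labels, "label_set": tuple(label_set),
    }


# ---------------------------------------------------------------------------
# training

class EarlyStopper:
    """Stop when validation loss fails to improve by more than ``tol`` for
    ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int, tol: float = 1e-4):
        self.patience = patience
        self.tol = tol
        self.best = math.inf
        self.best_epoch = 0
        self._stall = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        self.epoch += 1
        if loss < self.best - self.tol:
            self.best = loss
            self.best_epoch = self.epoch
            self._stall = 0
            return False
        self._stall += 1
        return self._stall >= self.patience


def _dataset_loss(model: DynamicGRNN, data: dict) -> float:
    out = model.forward(data["X"], data["E"], data["A"], training=False)
    return float(model.loss(out["probs"], data["y"]).data)


def train(model: DynamicGRNN, train_data: dict, val_data: dict,
          cfg: TrainConfig = TrainConfig()) -> tuple[dict, pd.DataFrame]:
    """Fit the model with Adam on mini-batches of subject graphs.

    Cross-entropy on shuffled mini-batches; after each epoch the validation
    loss is evaluated and early stopping applied; the parameters of the best
    validation epoch are restored and returned (also left on the model).
    Deterministic for a given config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD47A)))
    opt = Adam(model.params, lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience, cfg.tol)
    best_params = model.export_params()
    history = []
    n = len(train_data["y"])
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = train_data["X"][idx]
            if cfg.augment_sd > 0:
                xb = xb + cfg.augment_sd * rng.standard_normal(xb.shape)
            out = model.forward(xb, train_data["E"][idx],
                                train_data["A"][idx], training=True, rng=rng)
            loss = model.loss(out["probs"], train_data["y"][idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss.data})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_loss = _dataset_loss(model, val_data)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                        "val_loss": val_loss})
        stop = stopper.update(val_loss)
        if stopper.best_epoch == epoch:
            best_params = model.export_params()
        if stop:
            break
    model.set_params(best_params)
    return best_params, pd.DataFrame(history)


def evaluate(model: DynamicGRNN, data: dict) -> tuple[EvalMetrics, pd.DataFrame]:
    """Metrics over a test set plus the per-subject node-weight table.

    The node-weight table holds each subject's attention gate value per ROI
    (the quantity the pooling layer ranks), feeding the biomarker stage.
    """
    out = model.forward(data["X"], data["E"], data["A"], training=False)
    probs = out["probs"].data
    y_pred = probs.argmax(axis=1)
    y_true = data["y"]
    counts = confusion_counts(y_true, y_pred)
    metrics = compute_metrics(counts, scores=probs[:, 1], y_true=y_true)
    weights = pd.DataFrame(out["node_gates"], index=data["subject_ids"],
                           columns=data["roi_labels"])
    return metrics, weights


# ---------------------------------------------------------------------------
# biomarkers and sweeps

def biomarker_frequency(fold_weights: Sequence[np.ndarray], top_k: int = 10,
                        roi_labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Frequency ranking of the Top-K ROIs per fold across folds.

    Each fold contributes its ``top_k`` highest-weight ROIs (ties to the lower
    index); ROIs are ranked by appearance count, then mean weight, then index.
    """
    if len(fold_weights) == 0:
        raise ConfigError("need at least one fold")
    folds = [np.asarray(w, dtype=float) for w in fold_weights]
    n = len(folds[0])
    if top_k > n:
        warnings.warn(f"top_k={top_k} exceeds {n} ROIs; clipping", stacklevel=2)
        top_k = n
    counts = np.zeros(n, dtype=int)
    for w in folds:
        top = np.argsort(-w, kind="stable")[:top_k]
        counts[top] += 1
    mean_w = np.mean(folds, axis=0)
    order = sorted(range(n), key=lambda i: (-counts[i], -mean_w[i], i))
    labels = list(roi_labels) if roi_labels is not None else [str(i) for i in range(n)]
    return pd.DataFrame({
        "roi_index": order,
        "roi": [labels[i] for i in order],
        "frequency": counts[order],
        "mean_weight": mean_w[order],
    })


def run_split_experiment(
    subjects: Sequence[tuple[ROITimeSeries, str]],
    window: SlidingWindowConfig,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    split_seed: int,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    datasets: dict | None = None,
) -> dict:
    """One full train/validate/test cycle on a subject cohort.

    Splits subjects (stratified), trains, and returns test metrics plus the
    fold's mean node-weight vector. ``datasets`` may carry a precomputed
    ``prepare_dataset`` result for the whole cohort to avoid rebuilding
    graphs across repeated calls (keyed by subject order).
    """
    labels = [lbl for _, lbl in subjects]
    label_set = tuple(dict.fromkeys(labels))
    if datasets is None:
        datasets = prepare_dataset(subjects, window, label_set)
    idx_by_split = _stratified_index_split(labels, label_set, ratios, split_seed)

    def _subset(idx):
        return {
            "X": datasets["X"][idx], "E": datasets["E"][idx], "A": datasets["A"][idx],
            "y": datasets["y"][idx],
            "subject_ids": [datasets["subject_ids"][i] for i in idx],
            "roi_labels": datasets["roi_labels"], "label_set": datasets["label_set"],
        }

    model = DynamicGRNN(model_cfg)
    _, history = train(model, _subset(idx_by_split[0]), _subset(idx_by_split[1]), train_cfg)
    metrics, weights = evaluate(model, _subset(idx_by_split[2]))
    return {
        "metrics": metrics,
        "node_weights": weights.to_numpy().mean(axis=0),
        "weights_table": weights,
        "history": history,
        "split": idx_by_split,
    }


def leave_one_out(
    subjects: Sequence[tuple[ROITimeSeries, str]],
    window: SlidingWindowConfig,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    val_fraction: float = 0.25,
) -> tuple[EvalMetrics, pd.DataFrame]:
    """Leave-one-subject-out cross-validation.

    Each subject in turn is held out; the rest are split into train and
    validation (stratified), the model is retrained from scratch, and the
    held-out subject is scored. Returns pooled metrics over all held-out
    predictions plus the per-subject node-weight table. Expensive: one full
    training per subject.
    """
    labels = [lbl for _, lbl in subjects]
    label_set = tuple(dict.fromkeys(labels))
    datasets = prepare_dataset(subjects, window, label_set)
    n = len(subjects)
    y_true, y_pred, scores, weight_rows = [], [], [], []
    for held in range(n):
        rest = [i for i in range(n) if i != held]
        rest_labels = [labels[i] for i in rest]
        ratios = (1 - val_fraction, val_fraction, 0.0)
        tr_idx, va_idx, _ = _stratified_index_split(
            rest_labels, label_set, ratios, train_cfg.seed + held)

        def _subset(idx, source=rest):
            sel = np.array([source[i] for i in idx], dtype=int)
            return {
                "X": datasets["X"][sel], "E": datasets["E"][sel],
                "A": datasets["A"][sel], "y": datasets["y"][sel],
                "subject_ids": [datasets["subject_ids"][i] for i in sel],
                "roi_labels": datasets["roi_labels"],
                "label_set": datasets["label_set"],
            }

        model = DynamicGRNN(model_cfg)
        train(model, _subset(tr_idx), _subset(va_idx), train_cfg)
        out = model.forward(datasets["X"][held:held + 1],
                            datasets["E"][held:held + 1],
                            datasets["A"][held:held + 1])
        probs = out["probs"].data[0]
        y_true.append(int(datasets["y"][held]))
        y_pred.append(int(probs.argmax()))
        scores.append(float(probs[1]))
        weight_rows.append(out["node_gates"][0])
    metrics = compute_metrics(confusion_counts(y_true, y_pred),
                              scores=scores, y_true=y_true)
    weights = pd.DataFrame(weight_rows, index=datasets["subject_ids"],
                           columns=datasets["roi_labels"])
    return metrics, weights


def _stratified_index_split(labels, label_set, ratios, seed):
    """Index-level analogue of cohort splitting (largest remainder per group)."""
    from dyngrnn.cohort import _largest_remainder

    rng = np.random.default_rng(seed)
    buckets = [[], [], []]
    for g in label_set:
        members = [i for i, lbl in enumerate(labels) if lbl == g]
        perm = rng.permutation(len(members))
        sizes = _largest_remainder(len(members), ratios)
        pos = 0
        for b, size in enumerate(sizes):
            buckets[b].extend(members[j] for j in perm[pos:pos + size])
            pos += size
    return [np.array(sorted(b), dtype=int) for b in buckets]


def sweep_window(subjects, widths: Sequence[int], steps: Sequence[int],
                 model_cfg: ModelConfig, train_cfg: TrainConfig,
                 split_seed: int = 0) -> pd.DataFrame:
    """Test accuracy over a (width, step) grid; invalid cells yield NaN.

    Each cell runs an independent train/evaluate cycle with a seed keyed to
    the cell, so grid order never influences any value.
    """
    n_time = subjects[0][0].n_timepoints
    grid = np.full((len(widths), len(steps)), np.nan)
    for i, w in enumerate(widths):
        for j, s in enumerate(steps):
            if w < 2 or w > n_time or s < 1:
                continue
            cell_seed = int(np.random.SeedSequence((train_cfg.seed, w, s)).generate_state(1)[0] % (2 ** 31))
            cfg = replace(train_cfg, seed=cell_seed)
            res = run_split_experiment(subjects, SlidingWindowConfig(w, s),
                                       model_cfg, cfg, split_seed=split_seed)
            grid[i, j] = res["metrics"].accuracy
    return pd.DataFrame(grid, index=pd.Index(widths, name="width"),
                        columns=pd.Index(steps, name="step"))


def sweep_pooling_ratio(subjects, ratios: Sequence[float],
                        window: SlidingWindowConfig,
                        model_cfg: ModelConfig, train_cfg: TrainConfig,
                        split_seed: int = 0) -> pd.DataFrame:
    """Test accuracy as a function of the Top-K pooling ratio."""
    datasets = prepare_dataset(subjects, window)
    rows = []
    for r in ratios:
        cell_seed = int(np.random.SeedSequence(
            (train_cfg.seed, int(round(r * 1000)))).generate_state(1)[0] % (2 ** 31))
        cfg = replace(train_cfg, seed=cell_seed)
        mcfg = replace(model_cfg, pooling_ratio=r)
        res = run_split_experiment(subjects, window, mcfg, cfg,
                                   split_seed=split_seed, datasets=datasets)
        rows.append({"ratio": r, "accuracy": res["metrics"].accuracy})
    return pd.DataFrame(rows)
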