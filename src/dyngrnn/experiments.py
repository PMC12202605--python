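"""Reference synthetic-recovery experiments: cohort design and protocols.

This module fixes one study design — a two-group cohort whose patient class
carries a dynamic connectivity signature on five designated ROI pairs — and
provides the protocols built on it: repeated stratified train/val/test
cycles over seeds, a label-permutation null for the biomarker frequency
ranking, and the component ablation (full model vs. no pooling vs. a static
single-window graph).

Design of the recovery cohort: 90 ROIs in six communities of 15 with
within-community correlation 0.2; two covariance states alternating every 40
timepoints; in the second state the patient class gains +0.5 correlation on
five within-community ROI pairs (10 distinct ROIs). Controls' two states
coincide, so the class difference is purely dynamic: the affected pairs
alternate between baseline and elevated coupling while every whole-series
summary blurs the two. Observation noise sd 0.1.
"""

from __future__ import annotations

import numpy as np

from dyngrnn.dynamic import SlidingWindowConfig
from dyngrnn.nn.model import ModelConfig
from dyngrnn.synthetic import BlockStructure, SyntheticSpec, generate_cohort_arrays
from dyngrnn.train import (
    TrainConfig,
    biomarker_frequency,
    prepare_dataset,
    run_split_experiment,
)

__all__ = [
    "INJECTED_PAIRS",
    "INJECTED_ROIS",
    "recovery_spec",
    "recovery_window",
    "recovery_model_config",
    "recovery_train_config",
    "run_recovery_seeds",
    "biomarker_null",
    "run_ablation",
]

INJECTED_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 7), (15, 22), (30, 37), (45, 52), (60, 67),
)
INJECTED_ROIS: tuple[int, ...] = tuple(sorted(i for p in INJECTED_PAIRS for i in p))


def recovery_spec(seed: int, n_per_class: int = 40, delta: float = 0.5,
                  state_period: int = 40) -> SyntheticSpec:
    """The recovery cohort for one seed (90 ROIs x 198 timepoints)."""
    return SyntheticSpec(
        n_rois=90,
        n_timepoints=198,
        n_subjects_per_class={"control": n_per_class, "patient": n_per_class},
        block_structure=BlockStructure.even(90, 6, within=0.2, between=0.0),
        state_period=state_period,
        class_effects={"patient": [(i, j, delta) for i, j in INJECTED_PAIRS]},
        noise_sd=0.1,
        seed=seed,
    )


def recovery_window() -> SlidingWindowConfig:
    return SlidingWindowConfig(width=30, step=8)


def recovery_model_config(seed: int = 0, pooling_ratio: float | None = 0.2) -> ModelConfig:
    return ModelConfig(hidden_dim=8, cell_variant="gated", pooling_ratio=pooling_ratio,
                       dropout_p=0.1, mlp_hidden=16, n_classes=2, seed=seed)


def recovery_train_config(seed: int = 0, max_epochs: int = 60) -> TrainConfig:
    return TrainConfig(batch_size=16, learning_rate=3e-3, max_epochs=max_epochs,
                       patience=20, augment_sd=1.0, seed=seed)


def _experiment(subjects, datasets, seed: int, pooling_ratio, window,
                max_epochs: int) -> dict:
    res = run_split_experiment(
        subjects, window,
        recovery_model_config(seed=seed, pooling_ratio=pooling_ratio),
        recovery_train_config(seed=seed, max_epochs=max_epochs),
        split_seed=seed, datasets=datasets,
    )
    return res


def run_recovery_seeds(seeds=range(10), max_epochs: int = 60) -> dict:
    """Train/evaluate once per seed on freshly generated cohorts.

    Returns per-seed accuracies, AUCs and fold-level node-weight vectors
    (mean attention gate per ROI over the test subjects), plus the biomarker
    frequency table across the seed-folds.
    """
    window = recovery_window()
    accs, aucs, fold_weights = [], [], []
    for seed in seeds:
        subjects = generate_cohort_arrays(recovery_spec(seed))
        datasets = prepare_dataset(subjects, window)
        res = _experiment(subjects, datasets, seed, 0.2, window, max_epochs)
        accs.append(res["metrics"].accuracy)
        aucs.append(res["metrics"].auc)
        fold_weights.append(res["node_weights"])
    table = biomarker_frequency(fold_weights, top_k=10,
                                roi_labels=[f"ROI_{i + 1:03d}" for i in range(90)])
    return {"accuracies": np.array(accs), "aucs": np.array(aucs),
            "fold_weights": fold_weights, "biomarkers": table}


def injected_hit_count(fold_weights, top_k: int = 10) -> int:
    """Total appearances of injected ROIs in the per-fold top-k lists."""
    hits = 0
    inj = set(INJECTED_ROIS)
    for w in fold_weights:
        top = set(int(i) for i in np.argsort(-np.asarray(w), kind="stable")[:top_k])
        hits += len(top & inj)
    return hits


def biomarker_null(n_permutations: int = 20, max_epochs: int = 60,
                   base_seed: int = 10_000, cohort_seeds=range(10)) -> np.ndarray:
    """Label-shuffle null for the injected-ROI hit statistic.

    Each permutation regenerates one of the study cohorts, shuffles the class
    labels over subjects, retrains with the same protocol, and records how
    many injected ROIs land in the attention top-10. Returns the null hit
    counts (one per permutation, each on a single fold).
    """
    window = recovery_window()
    cohort_seeds = list(cohort_seeds)
    nulls = []
    for p in range(n_permutations):
        subjects = generate_cohort_arrays(
            recovery_spec(cohort_seeds[p % len(cohort_seeds)]))
        datasets = prepare_dataset(subjects, window)
        rng = np.random.default_rng(base_seed + p)
        perm = rng.permutation(len(datasets["y"]))
        shuffled = dict(datasets)
        shuffled["y"] = datasets["y"][perm]
        labels = [subjects[i][1] for i in perm]
        pseudo = [(ts, labels[k]) for k, (ts, _) in enumerate(subjects)]
        res = run_split_experiment(
            pseudo, window,
            recovery_model_config(seed=base_seed + p, pooling_ratio=0.2),
            recovery_train_config(seed=base_seed + p, max_epochs=max_epochs),
            split_seed=base_seed + p, datasets=shuffled,
        )
        nulls.append(injected_hit_count([res["node_weights"]]))
    return np.array(nulls)


def run_ablation(seeds=range(10), max_epochs: int = 60,
                 full_accuracies=None) -> dict:
    """Mean test accuracy of full model / no pooling / static single window.

    The static arm rebuilds the graphs with one full-length window, removing
    every dynamic feature (its edge features are all degenerate mid-scale),
    so it plays the whole-series-connectivity baseline. The full arm uses
    the same protocol as ``run_recovery_seeds``; pass its per-seed
    accuracies as ``full_accuracies`` to avoid retraining that arm.
    """
    window = recovery_window()
    seeds = list(seeds)
    acc = {"full": [], "no_pool": [], "static": []}
    if full_accuracies is not None:
        acc["full"] = list(full_accuracies)
        if len(acc["full"]) != len(seeds):
            raise ValueError("one full-model accuracy per seed required")
    for seed in seeds:
        subjects = generate_cohort_arrays(recovery_spec(seed))
        datasets = prepare_dataset(subjects, window)
        if full_accuracies is None:
            acc["full"].append(
                _experiment(subjects, datasets, seed, 0.2, window, max_epochs)["metrics"].accuracy)
        acc["no_pool"].append(
            _experiment(subjects, datasets, seed, None, window, max_epochs)["metrics"].accuracy)
        static_window = SlidingWindowConfig(width=198, step=198)
        static_data = prepare_dataset(subjects, static_window)
        res = run_split_experiment(
            subjects, static_window,
            recovery_model_config(seed=seed, pooling_ratio=0.2),
            recovery_train_config(seed=seed, max_epochs=max_epochs),
            split_seed=seed, datasets=static_data,
        )
        acc["static"].append(res["metrics"].accuracy)
    return {k: np.array(v) for k, v in acc.items()}
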