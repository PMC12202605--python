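"""Metrics, early stopping, training determinism, biomarkers and sweeps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from dyngrnn import (
    BlockStructure,
    DynamicGRNN,
    EarlyStopper,
    ModelConfig,
    SlidingWindowConfig,
    SyntheticSpec,
    TrainConfig,
    auc_score,
    biomarker_frequency,
    compute_metrics,
    confusion_counts,
    evaluate,
    generate_cohort_arrays,
    prepare_dataset,
    run_split_experiment,
    sweep_pooling_ratio,
    train,
)
from dyngrnn.exceptions import ConfigError, DimensionError


class TestConfusionAndMetrics:
    def test_perfect_prediction(self):
        assert confusion_counts([1, 1, 0], [1, 1, 0]) == (2, 0, 0, 1)

    def test_inverted_prediction(self):
        y = np.array([1, 0, 1, 0])
        tp, fn, fp, tn = confusion_counts(y, 1 - y)
        assert tp == 0 and tn == 0

    def test_matches_loop_oracle(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        tp, fn, fp, tn = confusion_counts(y_true, y_pred)
        otp = sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 1)
        ofn = sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 0)
        ofp = sum(1 for a, b in zip(y_true, y_pred) if a == 0 and b == 1)
        otn = sum(1 for a, b in zip(y_true, y_pred) if a == 0 and b == 0)
        assert (tp, fn, fp, tn) == (otp, ofn, ofp, otn)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            confusion_counts([1, 0], [1])

    def test_direct_arithmetic(self):
        m = compute_metrics((3, 1, 1, 5))
        assert m.accuracy == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_metric_identities_random_tables(self, rng):
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            m = compute_metrics((tp, fn, fp, tn))
            total = tp + fn + fp + tn
            assert m.accuracy == pytest.approx(1 - (fp + fn) / total)
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))

    def test_zero_denominator_flagged(self):
        m = compute_metrics((0, 0, 2, 3))
        assert m.recall == 0.0 and "recall" in m.degenerate

    def test_auc_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_auc_all_ties_half(self):
        assert auc_score([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_auc_single_class_undefined(self):
        assert auc_score([1, 1, 1], [0.1, 0.5, 0.9]) is None

    def test_auc_matches_sklearn(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, 40)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(40), 1)  # coarse scores force ties
            assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, 60)
        s = rng.random(60)
        assert auc_score(y, s) == pytest.approx(auc_score(y, np.exp(3 * s)))


class TestEarlyStopper:
    def test_spec_trace(self):
        # losses [1.0, 0.9, 0.95, 0.96], patience 2, tol 0:
        # stops after epoch 4, best epoch 2
        stop = EarlyStopper(patience=2, tol=0.0)
        outcomes = [stop.update(v) for v in [1.0, 0.9, 0.95, 0.96]]
        assert outcomes == [False, False, False, True]
        assert stop.best_epoch == 2

    def test_improvement_resets_counter(self):
        stop = EarlyStopper(patience=2, tol=0.0)
        for v in [1.0, 0.95, 0.96, 0.9, 0.91]:
            assert not stop.update(v)

    def test_tol_treats_small_gains_as_stall(self):
        stop = EarlyStopper(patience=2, tol=0.1)
        assert not stop.update(1.0)
        assert not stop.update(0.95)  # gain below tol -> stall 1
        assert stop.update(0.92)      # stall 2 -> stop
        assert stop.best_epoch == 1


def tiny_cohort(seed=0, n_per_class=8):
    spec = SyntheticSpec(
        n_rois=8, n_timepoints=60,
        n_subjects_per_class={"a": n_per_class, "b": n_per_class},
        block_structure=BlockStructure.even(8, 2, within=0.3),
        state_period=15,
        class_effects={"b": [(0, 4, 0.5)]},
        noise_sd=0.1, seed=seed)
    return generate_cohort_arrays(spec)


class TestTraining:
    def test_one_epoch_limit(self):
        subjects = tiny_cohort()
        ds = prepare_dataset(subjects, SlidingWindowConfig(10, 5))
        model = DynamicGRNN(ModelConfig(hidden_dim=3, seed=0))
        cfg = TrainConfig(batch_size=8, max_epochs=1, patience=1, seed=0)
        _, history = train(model, ds, ds, cfg)
        assert len(history) == 1

    def test_determinism(self):
        subjects = tiny_cohort()
        ds = prepare_dataset(subjects, SlidingWindowConfig(10, 5))
        finals = []
        for _ in range(2):
            model = DynamicGRNN(ModelConfig(hidden_dim=3, seed=5))
            cfg = TrainConfig(batch_size=8, max_epochs=4, patience=4, seed=5)
            _, history = train(model, ds, ds, cfg)
            finals.append(history.val_loss.iloc[-1])
        assert finals[0] == pytest.approx(finals[1], abs=1e-9)

    def test_best_epoch_restored(self):
        subjects = tiny_cohort()
        ds = prepare_dataset(subjects, SlidingWindowConfig(10, 5))
        model = DynamicGRNN(ModelConfig(hidden_dim=3, seed=1))
        cfg = TrainConfig(batch_size=8, max_epochs=6, patience=6, seed=1)
        params, history = train(model, ds, ds, cfg)
        best = history.val_loss.min()
        out = model.forward(ds["X"], ds["E"], ds["A"])
        refit = float(model.loss(out["probs"], ds["y"]).data)
        assert refit == pytest.approx(best, abs=1e-9)

    def test_evaluate_outputs(self):
        subjects = tiny_cohort()
        ds = prepare_dataset(subjects, SlidingWindowConfig(10, 5))
        model = DynamicGRNN(ModelConfig(hidden_dim=3, seed=2))
        metrics, weights = evaluate(model, ds)
        assert metrics.n == len(subjects)
        assert weights.shape == (len(subjects), 8)
        assert list(weights.columns) == list(ds["roi_labels"])

    def test_single_subject_auc_flagged(self):
        subjects = tiny_cohort()[:1]
        ds = prepare_dataset(subjects, SlidingWindowConfig(10, 5), label_set=("a", "b"))
        model = DynamicGRNN(ModelConfig(hidden_dim=3, seed=2))
        metrics, _ = evaluate(model, ds)
        assert metrics.auc is None and "auc" in metrics.degenerate


class TestBiomarkers:
    def test_unanimous_roi_ranks_first(self):
        folds = [np.array([0.1, 0.9, 0.2, 0.3]) for _ in range(3)]
        folds[1] = np.array([0.15, 0.8, 0.25, 0.1])
        table = biomarker_frequency(folds, top_k=1)
        assert table.iloc[0]["roi_index"] == 1
        assert table.iloc[0]["frequency"] == 3

    def test_identical_folds_equal_single_fold(self, rng):
        w = rng.random(12)
        multi = biomarker_frequency([w, w, w], top_k=5)
        single = biomarker_frequency([w], top_k=5)
        assert multi.roi_index.tolist() == single.roi_index.tolist()

    def test_matches_counting_oracle(self, rng):
        folds = [rng.random(15) for _ in range(6)]
        top_k = 4
        table = biomarker_frequency(folds, top_k=top_k)
        counts = np.zeros(15, dtype=int)
        for w in folds:
            for i in sorted(range(15), key=lambda i: (-w[i], i))[:top_k]:
                counts[i] += 1
        for _, row in table.iterrows():
            assert counts[row.roi_index] == row.frequency
        assert table.frequency.is_monotonic_decreasing

    def test_top_k_clipped_with_warning(self, rng):
        with pytest.warns(UserWarning):
            biomarker_frequency([rng.random(4)], top_k=10)


class TestSweeps:
    def test_pooling_sweep_rows_and_determinism(self):
        subjects = tiny_cohort()
        mc = ModelConfig(hidden_dim=3, seed=0)
        tc = TrainConfig(batch_size=8, max_epochs=2, patience=2, seed=0)
        window = SlidingWindowConfig(10, 5)
        ratios = [0.5, 1.0]
        a = sweep_pooling_ratio(subjects, ratios, window, mc, tc)
        b = sweep_pooling_ratio(subjects, ratios, window, mc, tc)
        assert len(a) == 2
        pd.testing.assert_frame_equal(a, b)

    def test_leave_one_out_pools_every_subject(self):
        from dyngrnn.train import leave_one_out

        subjects = tiny_cohort(n_per_class=3)
        metrics, weights = leave_one_out(
            subjects, SlidingWindowConfig(10, 10),
            ModelConfig(hidden_dim=2, mlp_hidden=4, seed=0),
            TrainConfig(batch_size=4, max_epochs=2, patience=2, seed=0))
        assert metrics.n == 6
        assert weights.shape == (6, 8)

    def test_split_experiment_runs_end_to_end(self):
        subjects = tiny_cohort(n_per_class=10)
        res = run_split_experiment(
            subjects, SlidingWindowConfig(10, 5),
            ModelConfig(hidden_dim=3, seed=0),
            TrainConfig(batch_size=8, max_epochs=3, patience=3, seed=0),
            split_seed=0, ratios=(0.5, 0.25, 0.25))
        assert 0.0 <= res["metrics"].accuracy <= 1.0
        assert res["node_weights"].shape == (8,)
        tr, va, te = res["split"]
        assert len(set(tr) | set(va) | set(te)) == 20


def test_train_config_validation():
    with pytest.raises(ConfigError):
        TrainConfig(patience=10, max_epochs=5)
    with pytest.raises(ConfigError):
        TrainConfig(learning_rate=0)
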