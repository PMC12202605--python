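"""Recurrent cells, attention pooling, readout, classifier head and gradients."""

import math

import numpy as np
import pytest

from dyngrnn import DynamicGRNN, ModelConfig, ROITimeSeries, SlidingWindowConfig, build_dynamic_graph
from dyngrnn.nn.autograd import Tensor
from dyngrnn.nn.model import (
    classify,
    grnn_cell_dual,
    grnn_cell_gated,
    grnn_cell_simple,
    grnn_forward,
    n_kept,
    readout,
    sag_pool,
)


def random_edges(rng, B, n, m):
    E = rng.random((B, n, n, m))
    E = (E + E.transpose(0, 2, 1, 3)) / 2
    for b in range(B):
        for t in range(m):
            np.fill_diagonal(E[b, :, :, t], 0)
    return E


class TestCells:
    def test_simple_zero_weights(self, rng):
        h = grnn_cell_simple(rng.standard_normal((4, 3)),
                             np.zeros((4, 4)), np.zeros((3, 3)), np.zeros(3))
        np.testing.assert_array_equal(h.data, 0.0)

    def test_simple_hand_example(self):
        h = grnn_cell_simple([[1.0], [2.0]], [[0, 0.5], [0.5, 0]], [[1.0]], [0.0])
        np.testing.assert_allclose(h.data, [[2.0], [2.5]])

    def test_simple_no_edges_no_mixing(self, rng):
        h_prev = rng.standard_normal((5, 2))
        w, b = rng.standard_normal((2, 2)), rng.standard_normal(2)
        h = grnn_cell_simple(h_prev, np.zeros((5, 5)), w, b)
        for i in range(5):
            solo = grnn_cell_simple(h_prev[i:i + 1], np.zeros((1, 1)), w, b)
            np.testing.assert_allclose(h.data[i], solo.data[0], atol=1e-12)

    def test_dual_ignores_edges_when_wneigh_zero(self, rng):
        h_prev = rng.standard_normal((4, 3))
        ws, b = rng.standard_normal((3, 3)), rng.standard_normal(3)
        e1, e2 = random_edges(rng, 1, 4, 2)[0, :, :, 0], np.zeros((4, 4))
        a = grnn_cell_dual(h_prev, e1, ws, np.zeros((3, 3)), b)
        c = grnn_cell_dual(h_prev, e2, ws, np.zeros((3, 3)), b)
        np.testing.assert_allclose(a.data, c.data)

    def test_dual_reduces_to_simple(self, rng):
        h_prev = rng.standard_normal((4, 3))
        e = random_edges(rng, 1, 4, 1)[0, :, :, 0]
        w, b = rng.standard_normal((3, 3)), rng.standard_normal(3)
        np.testing.assert_allclose(
            grnn_cell_dual(h_prev, e, w, w, b).data,
            grnn_cell_simple(h_prev, e, w, b).data, atol=1e-12)

    def test_dual_matches_loop_oracle(self, rng):
        n, H = 3, 2
        h_prev = rng.standard_normal((n, H))
        e = random_edges(rng, 1, n, 1)[0, :, :, 0]
        ws, wn, b = (rng.standard_normal((H, H)), rng.standard_normal((H, H)),
                     rng.standard_normal(H))
        out = grnn_cell_dual(h_prev, e, ws, wn, b).data
        for i in range(n):
            msg = sum(e[i, j] * h_prev[j] for j in range(n) if j != i)
            expect = np.maximum(ws @ h_prev[i] + wn @ msg + b, 0)
            np.testing.assert_allclose(out[i], expect, atol=1e-12)

    def _gate_params(self, rng, H):
        return {
            **{f"gate_W{g}": rng.standard_normal((4 * H + 1, H)) * 0.3
               for g in "ifoc"},
            **{f"gate_b{g}": rng.standard_normal(H) * 0.1 for g in "ifoc"},
        }

    def test_gated_output_identity(self, rng):
        n, H = 3, 4
        params = self._gate_params(rng, H)
        h, c = grnn_cell_gated(rng.standard_normal((n, H)), rng.standard_normal((n, H)),
                               rng.standard_normal((n, H)),
                               random_edges(rng, 1, n, 1)[0, :, :, 0], params)
        # defining relation: h = o * tanh(C), with o in (0, 1)
        ratio = h.data / np.tanh(c.data)
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_gated_closed_output_gate(self, rng):
        n, H = 3, 4
        params = self._gate_params(rng, H)
        params["gate_Wo"] = np.zeros((4 * H + 1, H))
        params["gate_bo"] = np.full(H, -50.0)
        h, _ = grnn_cell_gated(rng.standard_normal((n, H)), rng.standard_normal((n, H)),
                               rng.standard_normal((n, H)),
                               random_edges(rng, 1, n, 1)[0, :, :, 0], params)
        np.testing.assert_allclose(h.data, 0.0, atol=1e-12)

    def test_gated_memory_passthrough(self, rng):
        n, H = 3, 4
        params = self._gate_params(rng, H)
        params["gate_Wf"] = np.zeros((4 * H + 1, H))
        params["gate_bf"] = np.full(H, 50.0)   # forget gate ~ 1
        params["gate_Wi"] = np.zeros((4 * H + 1, H))
        params["gate_bi"] = np.full(H, -50.0)  # input gate ~ 0
        c_prev = rng.standard_normal((n, H))
        _, c = grnn_cell_gated(rng.standard_normal((n, H)), c_prev,
                               rng.standard_normal((n, H)),
                               random_edges(rng, 1, n, 1)[0, :, :, 0], params)
        np.testing.assert_allclose(c.data, c_prev, atol=1e-10)


class TestPooling:
    def test_keep_all(self, rng):
        X = rng.standard_normal((6, 3))
        A = random_edges(rng, 1, 6, 1)[0, :, :, 0]
        res = sag_pool(X, A, 1.0, rng.standard_normal((3, 1)), rng.standard_normal((3, 1)))
        np.testing.assert_array_equal(res.idx, np.arange(6))
        np.testing.assert_allclose(res.pooled_adjacency, A)
        np.testing.assert_allclose(res.pooled_features, X * res.gates[:, None])

    def test_counts_on_grid(self):
        for n in range(1, 121):
            for k in np.arange(0.05, 1.01, 0.05):
                assert n_kept(n, float(k)) == min(max(1, math.ceil(k * n)), n)
        assert n_kept(90, 0.2) == 18

    def test_ranking_preserved_through_gates(self, rng):
        # softmax and tanh are strictly increasing: ranking equals score ranking
        z = np.array([0.1, 0.9, 0.3, 0.2, 0.5])
        X = z[:, None] * np.ones((5, 1))
        res = sag_pool(X, np.zeros((5, 5)), 0.4, np.ones((1, 1)), np.zeros((1, 1)))
        np.testing.assert_array_equal(res.idx, [1, 4])

    def test_pooled_structure(self, rng):
        X = rng.standard_normal((10, 4))
        A = random_edges(rng, 1, 10, 1)[0, :, :, 0]
        res = sag_pool(X, A, 0.3, rng.standard_normal((4, 1)), rng.standard_normal((4, 1)))
        assert len(res.idx) == 3
        assert np.all(np.diff(res.idx) > 0)  # ascending original ids
        np.testing.assert_allclose(res.pooled_adjacency, A[np.ix_(res.idx, res.idx)])
        np.testing.assert_allclose(res.pooled_features,
                                   X[res.idx] * res.node_gates[res.idx][:, None])

    def test_gate_variants_agree_on_selection(self, rng):
        X = rng.standard_normal((8, 3))
        A = random_edges(rng, 1, 8, 1)[0, :, :, 0]
        ws, wn = rng.standard_normal((3, 1)), rng.standard_normal((3, 1))
        a = sag_pool(X, A, 0.5, ws, wn, gate="softmax_tanh")
        b = sag_pool(X, A, 0.5, ws, wn, gate="tanh")
        np.testing.assert_array_equal(a.idx, b.idx)


class TestReadoutClassify:
    def test_single_node_readout(self, rng):
        x = rng.standard_normal((1, 4))
        out = readout(x).data
        np.testing.assert_allclose(out, np.concatenate([x[0], x[0]]))

    def test_duplicate_rows_idempotent(self, rng):
        x = rng.standard_normal((1, 3))
        np.testing.assert_allclose(readout(np.repeat(x, 4, axis=0)).data,
                                   readout(x).data)

    def test_readout_matches_mean_max(self, rng):
        x = rng.standard_normal((4, 3))
        out = readout(x).data
        np.testing.assert_allclose(out[:3], x.mean(0))
        np.testing.assert_allclose(out[3:], x.max(0))

    def _mlp(self, rng, din, hidden, classes):
        return {"mlp_W1": rng.standard_normal((din, hidden)),
                "mlp_b1": rng.standard_normal(hidden),
                "mlp_W2": rng.standard_normal((hidden, classes)),
                "mlp_b2": rng.standard_normal(classes)}

    def test_zero_weights_uniform(self, rng):
        params = {k: np.zeros_like(v) for k, v in self._mlp(rng, 4, 3, 3).items()}
        probs = classify(rng.standard_normal(4), params).data
        np.testing.assert_allclose(probs, 1 / 3)

    def test_probabilities_normalized(self, rng):
        params = self._mlp(rng, 4, 5, 4)
        for _ in range(20):
            p = classify(rng.standard_normal(4), params).data
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p >= 0)

    def test_eval_mode_ignores_dropout_seed(self, rng):
        params = self._mlp(rng, 4, 5, 2)
        x = rng.standard_normal(4)
        a = classify(x, params, dropout_p=0.5, training=False)
        b = classify(x, params, dropout_p=0.5, training=False,
                     rng=np.random.default_rng(999))
        np.testing.assert_array_equal(a.data, b.data)


class TestForward:
    def _graph(self, rng, n=4, K=24, w=8, s=4):
        ts = ROITimeSeries("s", tuple(f"R{i}" for i in range(n)),
                           rng.standard_normal((n, K)))
        return build_dynamic_graph(ts, SlidingWindowConfig(w, s))

    def test_single_window_is_embedding(self, rng):
        g = self._graph(rng, K=8, w=8, s=8)
        model = DynamicGRNN(ModelConfig(hidden_dim=3, cell_variant="simple", seed=0))
        with pytest.warns(UserWarning, match="single window"):
            h = grnn_forward(g, model)
        expect = (g.node_features[:, 0:1] @ model.params["embed_w"].data
                  + model.params["embed_b"].data)
        np.testing.assert_allclose(h, expect, atol=1e-12)

    @pytest.mark.parametrize("variant", ["simple", "dual", "gated"])
    def test_forward_permutation_equivariance(self, rng, variant):
        g = self._graph(rng, n=5)
        model = DynamicGRNN(ModelConfig(hidden_dim=4, cell_variant=variant, seed=1))
        h = model.encode(g.node_features[None], g.edge_features[None]).data[0]
        perm = np.array([2, 0, 4, 1, 3])
        hp = model.encode(g.node_features[perm][None],
                          g.edge_features[np.ix_(perm, perm)][None]).data[0]
        np.testing.assert_allclose(hp, h[perm], atol=1e-9)

    def test_simple_two_step_hand_rolled(self, rng):
        # 3 nodes, 2 windows, H=1: embedding then one simple-cell step
        n = 3
        ts = ROITimeSeries("s", ("a", "b", "c"), rng.standard_normal((n, 8)))
        g = build_dynamic_graph(ts, SlidingWindowConfig(4, 4))
        model = DynamicGRNN(ModelConfig(hidden_dim=1, cell_variant="simple", seed=2))
        h = grnn_forward(g, model)
        we = model.params["embed_w"].data[0, 0]
        be = model.params["embed_b"].data[0]
        w = model.params["cell_W"].data[0, 0]
        b = model.params["cell_b"].data[0]
        h0 = we * g.node_features[:, 0] + be
        scale = 1.0 / math.sqrt(n - 1)
        e = g.edge_features[:, :, 0] * scale
        np.fill_diagonal(e, 0)
        expect = np.maximum(w * (h0 + e @ h0) + b, 0)
        np.testing.assert_allclose(h[:, 0], expect, atol=1e-12)

    @pytest.mark.parametrize("variant", ["simple", "dual", "gated"])
    def test_forward_finite_for_random_parameters(self, rng, variant):
        g = self._graph(rng, n=6, K=40, w=8, s=4)
        A = g.mean_adjacency()
        for draw in range(30):
            model = DynamicGRNN(ModelConfig(hidden_dim=5, cell_variant=variant,
                                            seed=draw))
            for p in model.params.values():
                p.data = rng.standard_normal(p.data.shape)
            out = model.forward(g.node_features[None], g.edge_features[None], A[None])
            assert np.all(np.isfinite(out["probs"].data))

    def test_pool_consistency_under_relabeling(self, rng):
        g = self._graph(rng, n=6)
        model = DynamicGRNN(ModelConfig(hidden_dim=4, cell_variant="dual",
                                        pooling_ratio=0.5, seed=3))
        A = g.mean_adjacency()
        out = model.forward(g.node_features[None], g.edge_features[None], A[None])
        perm = np.array([5, 3, 0, 1, 4, 2])
        outp = model.forward(g.node_features[perm][None],
                             g.edge_features[np.ix_(perm, perm)][None],
                             A[np.ix_(perm, perm)][None])
        kept = set(out["kept_idx"][0].tolist())
        keptp = {int(perm[i]) for i in range(6) if i in outp["kept_idx"][0]}
        assert {int(perm.tolist().index(i)) for i in kept} == set(outp["kept_idx"][0].tolist()) or kept == keptp


class TestGradients:
    def test_numeric_vs_analytic_full_model(self, rng):
        # tiny instance: 5 nodes, 3 windows, hidden 4
        n, K, w, s = 5, 12, 4, 4
        ts = ROITimeSeries("s", tuple(f"R{i}" for i in range(n)),
                           rng.standard_normal((n, K)))
        g = build_dynamic_graph(ts, SlidingWindowConfig(w, s))
        assert g.n_windows == 3
        X, E, A = g.node_features[None], g.edge_features[None], g.mean_adjacency()[None]
        y = np.array([1])
        model = DynamicGRNN(ModelConfig(hidden_dim=4, cell_variant="gated",
                                        pooling_ratio=0.6, dropout_p=0.0,
                                        mlp_hidden=4, seed=4))

        def loss_value():
            out = model.forward(X, E, A)
            return model.loss(out["probs"], y)

        loss = loss_value()
        for p in model.params.values():
            p.grad = None
        loss.backward()
        check_rng = np.random.default_rng(0)
        for name, p in model.params.items():
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps = 1e-6
                old = flat[i]
                flat[i] = old + eps
                lp = float(loss_value().data)
                flat[i] = old - eps
                lm = float(loss_value().data)
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = grad.ravel()[i]
                assert abs(numeric - analytic) <= 1e-4 * max(1.0, abs(numeric)), (
                    f"{name}[{i}]: numeric {numeric}, analytic {analytic}")
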