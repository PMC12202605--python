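"""Recurrent graph encoder, self-attention Top-K pooling and classifier head.

Node states evolve across sliding windows: at each step a node's new state is
computed from its own previous state and its neighbors' states weighted by
that window's normalized edge strengths. Three cell variants are provided —
``simple`` (one shared weight for self and neighbor terms), ``dual``
(separate self/neighbor weights so connection strength acts as an adaptive
regulator), and ``gated`` (input/forget/output gates with a cell memory,
whose output is o * tanh(C)). After the final step a one-channel graph
convolution scores every node, the scores are softmax-then-tanh gated, the
Top ceil(k*n) nodes are kept, and a mean||max readout feeds a two-layer ReLU
perceptron with softmax output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from dyngrnn.exceptions import ConfigError, DimensionError
from dyngrnn.nn.autograd import Tensor, concat, stack_rows

__all__ = [
    "ModelConfig",
    "PoolingResult",
    "grnn_cell_simple",
    "grnn_cell_dual",
    "grnn_cell_gated",
    "grnn_forward",
    "sag_pool",
    "readout",
    "classify",
    "DynamicGRNN",
]

def _zero_diagonal(E: np.ndarray) -> np.ndarray:
    """Copy of an edge tensor (..., n, n) or (B, n, n, m) with zeroed self-edges."""
    E = np.array(E, dtype=float)
    n = E.shape[1] if E.ndim == 4 else E.shape[-1]
    if E.ndim == 4:
        E[:, np.arange(n), np.arange(n), :] = 0.0
    else:
        E[..., np.arange(n), np.arange(n)] = 0.0
    return E


_CELLS = ("simple", "dual", "gated")
_GATES = ("softmax_tanh", "tanh")


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 8
    cell_variant: str = "gated"
    pooling_ratio: float | None = 0.2  # None disables the pooling layer
    pool_gate: str = "softmax_tanh"
    dropout_p: float = 0.1
    mlp_hidden: int = 16
    n_classes: int = 2
    temporal_kernel: int = 5  # length of the state-trajectory convolution
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1 or self.mlp_hidden < 1:
            raise ConfigError("hidden sizes must be positive")
        if self.cell_variant not in _CELLS:
            raise ConfigError(f"cell_variant must be one of {_CELLS}")
        if self.pool_gate not in _GATES:
            raise ConfigError(f"pool_gate must be one of {_GATES}")
        if self.pooling_ratio is not None and not 0 < self.pooling_ratio <= 1:
            raise ConfigError("pooling_ratio must lie in (0, 1]")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must lie in [0, 1)")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")
        if self.temporal_kernel < 1:
            raise ConfigError("temporal_kernel must be >= 1")


# ---------------------------------------------------------------------------
# recurrent cells (single graph; arrays or Tensors in, Tensor out)

def _check_cell_shapes(h_prev, e_prev):
    if h_prev.data.ndim < 2:
        raise DimensionError("h_prev must be (n, H)")
    if e_prev.data.shape[-1] != h_prev.data.shape[-2]:
        raise DimensionError(
            f"edge matrix {e_prev.data.shape} incompatible with states {h_prev.data.shape}"
        )


def grnn_cell_simple(h_prev, e_prev, w, b) -> Tensor:
    """h_i = ReLU(W (h_i + sum_j E_ij h_j) + b)."""
    h_prev, e_prev = Tensor.as_tensor(h_prev), Tensor.as_tensor(e_prev)
    w, b = Tensor.as_tensor(w), Tensor.as_tensor(b)
    _check_cell_shapes(h_prev, e_prev)
    mixed = h_prev + e_prev @ h_prev
    return (mixed @ _transpose(w) + b).relu()


def grnn_cell_dual(h_prev, e_prev, w_self, w_neigh, b) -> Tensor:
    """h_i = ReLU(W_self h_i + W_neigh sum_j E_ij h_j + b)."""
    h_prev, e_prev = Tensor.as_tensor(h_prev), Tensor.as_tensor(e_prev)
    _check_cell_shapes(h_prev, e_prev)
    w_self, w_neigh, b = (Tensor.as_tensor(t) for t in (w_self, w_neigh, b))
    msg = e_prev @ h_prev
    return (h_prev @ _transpose(w_self) + msg @ _transpose(w_neigh) + b).relu()


def grnn_cell_gated(h_prev, c_prev, x_t, e_prev, params: dict) -> tuple[Tensor, Tensor]:
    """Gated recurrence with cell memory; output h = o * tanh(C).

    Gates i, f, o and the candidate are logistic/tanh maps of the
    concatenation [x_t, h_prev, state message E h_prev, input message E x_t,
    node strength sum_j E_ij]; C = f*C_prev + i*g. The input message pairs
    the current window's edge strengths with that window's node features, so
    gate products can express edge-weighted feature co-fluctuation, and the
    node-strength channel exposes each region's total connection strength per
    window — the weighted-degree trajectory that dynamic-connectivity studies
    track — directly to the memory.
    """
    h_prev, c_prev = Tensor.as_tensor(h_prev), Tensor.as_tensor(c_prev)
    x_t, e_prev = Tensor.as_tensor(x_t), Tensor.as_tensor(e_prev)
    _check_cell_shapes(h_prev, e_prev)
    msg = e_prev @ h_prev
    strength = e_prev.sum(axis=-1, keepdims=True)
    strength = strength - strength.mean(axis=-2, keepdims=True)  # center per graph
    z = concat([x_t, h_prev, msg, e_prev @ x_t, strength], axis=-1)
    gi = (z @ Tensor.as_tensor(params["gate_Wi"]) + Tensor.as_tensor(params["gate_bi"])).sigmoid()
    gf = (z @ Tensor.as_tensor(params["gate_Wf"]) + Tensor.as_tensor(params["gate_bf"])).sigmoid()
    go = (z @ Tensor.as_tensor(params["gate_Wo"]) + Tensor.as_tensor(params["gate_bo"])).sigmoid()
    gc = (z @ Tensor.as_tensor(params["gate_Wc"]) + Tensor.as_tensor(params["gate_bc"])).tanh()
    c = gf * c_prev + gi * gc
    h = go * c.tanh()
    return h, c


def _transpose(t: Tensor) -> Tensor:
    data = t.data

    def bwd(g):
        if t.requires_grad:
            t._accumulate(np.swapaxes(g, -1, -2))

    return Tensor(np.swapaxes(data, -1, -2), parents=(t,), backward=bwd)


# ---------------------------------------------------------------------------
# pooling / readout / classifier

@dataclass(frozen=True)
class PoolingResult:
    idx: np.ndarray        # kept node ids, ascending, size ceil(k*n)
    scores: np.ndarray     # raw attention score z per node, shape (n,)
    node_gates: np.ndarray  # gate value per node (all nodes), shape (n,)
    gates: np.ndarray      # gate values of the kept nodes
    pooled_features: np.ndarray  # (kept, H), gated rows
    pooled_adjacency: np.ndarray  # (kept, kept)


def n_kept(n: int, ratio: float) -> int:
    """Number of nodes the pooling layer keeps: ceil(ratio * n), at least 1."""
    k = math.ceil(ratio * n)
    if k < 1:
        warnings.warn("pooling ratio keeps no node; keeping 1", stacklevel=2)
        k = 1
    return min(k, n)


def _pool_core(x: Tensor, a: np.ndarray, ratio: float, w_self, w_neigh,
               gate: str = "softmax_tanh"):
    """Batched pooling core: x (B, n, H), a (B, n, n) constant adjacency."""
    w_self, w_neigh = Tensor.as_tensor(w_self), Tensor.as_tensor(w_neigh)
    a_t = Tensor.as_tensor(a)
    z = x @ w_self + a_t @ (x @ w_neigh)  # (B, n, 1) one-channel GraphConv
    if gate == "softmax_tanh":
        gates = z.softmax(axis=-2).tanh()
    else:
        gates = z.tanh()
    n = x.data.shape[-2]
    kept = n_kept(n, ratio)
    # stable argsort on -gates: ties resolved toward the lower node index
    order = np.argsort(-gates.data[..., 0], axis=-1, kind="stable")[..., :kept]
    idx = np.sort(order, axis=-1)
    x_kept = x.gather_rows(idx)
    g_kept = gates.gather_rows(idx)
    x_pooled = x_kept * g_kept
    a_pooled = np.stack([a[b][np.ix_(idx[b], idx[b])] for b in range(a.shape[0])])
    return x_pooled, a_pooled, idx, z, gates


def sag_pool(x, a: np.ndarray, ratio: float, w_self, w_neigh,
             gate: str = "softmax_tanh") -> PoolingResult:
    """Self-attention Top-K pooling of one graph.

    A one-channel graph convolution scores each node from its own features and
    its neighbors'; scores pass through softmax-then-tanh (or plain tanh — both
    strictly increasing, so the Top-K selection is identical); the ceil(k*n)
    best-gated nodes are kept (ascending ids), their feature rows gated, and
    the adjacency restricted to the kept rows/columns.
    """
    x = Tensor.as_tensor(x)
    a = np.asarray(a, dtype=float)
    xp, ap, idx, z, gates = _pool_core(
        x.reshape(1, *x.data.shape), a[None], ratio, w_self, w_neigh, gate
    )
    return PoolingResult(
        idx=idx[0],
        scores=z.data[0, :, 0],
        node_gates=gates.data[0, :, 0],
        gates=gates.data[0, :, 0][idx[0]],
        pooled_features=xp.data[0],
        pooled_adjacency=ap[0],
    )


def readout(x) -> Tensor:
    """Graph embedding: concatenation of node-wise mean and max (size 2H)."""
    x = Tensor.as_tensor(x)
    return concat([x.mean(axis=-2), x.max(axis=-2)], axis=-1)


def classify(embedding, params: dict, dropout_p: float = 0.0,
             training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
    """Two-layer ReLU perceptron with softmax output over the classes.

    Dropout (inverted scaling) acts on the pooled representation only in
    training mode; evaluation is deterministic.
    """
    e = Tensor.as_tensor(embedding)
    if training and dropout_p > 0:
        if rng is None:
            raise ConfigError("training-mode dropout needs a random generator")
        mask = (rng.random(e.data.shape) >= dropout_p) / (1.0 - dropout_p)
        e = e * mask
    h = (e @ Tensor.as_tensor(params["mlp_W1"]) + Tensor.as_tensor(params["mlp_b1"])).relu()
    logits = h @ Tensor.as_tensor(params["mlp_W2"]) + Tensor.as_tensor(params["mlp_b2"])
    return logits.softmax(axis=-1)


# ---------------------------------------------------------------------------
# full model

class DynamicGRNN:
    """The full classifier over dynamic graphs, with batched forward pass.

    Inputs are stacked per subject: node features X (B, n, m), normalized edge
    features E (B, n, n, m) and a pooling adjacency A (B, n, n) (by default
    the window-averaged normalized adjacency). Neighbor messages use the edge
    matrix scaled by 1/(n-1) (mean aggregation) so state magnitudes stay
    bounded regardless of graph size.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = self._init_params(config)

    # -- parameters -------------------------------------------------------
    @staticmethod
    def _glorot(rng, shape):
        fan_in, fan_out = shape[0], shape[-1]
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    def _init_params(self, cfg: ModelConfig) -> dict[str, Tensor]:
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden_dim
        p: dict[str, np.ndarray] = {
            "embed_w": self._glorot(rng, (1, H)),
            "embed_b": np.zeros(H),
        }
        if cfg.cell_variant == "simple":
            p["cell_W"] = self._glorot(rng, (H, H))
            p["cell_b"] = np.zeros(H)
        elif cfg.cell_variant == "dual":
            p["cell_Ws"] = self._glorot(rng, (H, H))
            p["cell_Wn"] = self._glorot(rng, (H, H))
            p["cell_b"] = np.zeros(H)
        else:
            for gate in ("i", "f", "o", "c"):
                p[f"gate_W{gate}"] = self._glorot(rng, (4 * H + 1, H))
                p[f"gate_b{gate}"] = np.zeros(H)
            p["gate_bf"] = np.ones(H)  # open forget gate at init
        for l in range(cfg.temporal_kernel):
            p[f"tc_W{l}"] = self._glorot(rng, (H + 1, H))
        p["tc_b"] = np.zeros(H)
        p["pool_ws"] = self._glorot(rng, (2 * H, 1))
        p["pool_wn"] = self._glorot(rng, (2 * H, 1))
        p["mlp_W1"] = self._glorot(rng, (4 * H, cfg.mlp_hidden))
        p["mlp_b1"] = np.zeros(cfg.mlp_hidden)
        p["mlp_W2"] = self._glorot(rng, (cfg.mlp_hidden, cfg.n_classes))
        p["mlp_b2"] = np.zeros(cfg.n_classes)
        return {k: Tensor(v, requires_grad=True) for k, v in p.items()}

    def set_params(self, values: dict[str, np.ndarray]):
        for k, v in values.items():
            self.params[k].data = np.array(v, dtype=float)

    def export_params(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    # -- forward ----------------------------------------------------------
    def _embed(self, x_col: np.ndarray) -> Tensor:
        # x_col: (B, n) scalar node feature -> (B, n, H) linear embedding
        return Tensor(x_col[..., None]) @ self.params["embed_w"] + self.params["embed_b"]

    def encode(self, X: np.ndarray, E: np.ndarray,
               return_history: bool = False) -> Tensor | list[Tensor]:
        """Run the recurrent encoder.

        Returns the final node states (B, n, H), or — with ``return_history``
        — the full per-window state trajectory as a list of (B, n, H) tensors.
        """
        cfg = self.config
        B, n, m = X.shape
        E = _zero_diagonal(E)  # self-loops are never part of the graph
        # 1/sqrt(n-1) keeps neighbor messages at unit scale for zero-mean
        # features while preventing the raw sum from growing with graph size
        scale = 1.0 / math.sqrt(max(n - 1, 1))
        h = self._embed(X[:, :, 0])
        history = [h]
        if m < 2:
            warnings.warn("single window: encoder reduces to the input embedding",
                          stacklevel=2)
            return history if return_history else h
        if cfg.cell_variant == "gated":
            c = Tensor(np.zeros_like(h.data))
        for t in range(1, m):
            e_t = E[:, :, :, t - 1] * scale
            if cfg.cell_variant == "simple":
                h = grnn_cell_simple(h, e_t, self.params["cell_W"], self.params["cell_b"])
            elif cfg.cell_variant == "dual":
                h = grnn_cell_dual(h, e_t, self.params["cell_Ws"],
                                   self.params["cell_Wn"], self.params["cell_b"])
            else:
                h, c = grnn_cell_gated(h, c, self._embed(X[:, :, t]), e_t, self.params)
            history.append(h)
        return history if return_history else h

    def temporal_pattern(self, history: list[Tensor],
                         strengths: np.ndarray | None = None) -> Tensor:
        """Turn each node's state trajectory into an evolution-pattern vector.

        A learned temporal convolution slides over the per-window node
        descriptors — the recurrent state concatenated with the node's
        centered connection strength for that window — and the filter
        responses are summarized by their mean and maximum over time. Node
        selection can therefore reflect how a region's connectivity evolves
        (e.g., locking to a rhythm of state switches), not just where its
        state ends up. Output shape (B, n, 2H).
        """
        m = len(history)
        B, n, _ = history[0].data.shape
        if strengths is None:
            strengths = np.zeros((B, n, m))
        traj = [concat([history[t], Tensor(strengths[:, :, t, None])], axis=-1)
                for t in range(m)]
        L = min(self.config.temporal_kernel, m)
        T = m - L + 1
        responses = []
        for t in range(T):
            acc = traj[t] @ self.params["tc_W0"]
            for l in range(1, L):
                acc = acc + traj[t + l] @ self.params[f"tc_W{l}"]
            responses.append((acc + self.params["tc_b"]).relu())
        stack = stack_rows(responses)  # (T, B, n, H)
        return concat([stack.mean(axis=0), stack.max(axis=0)], axis=-1)

    def forward(self, X: np.ndarray, E: np.ndarray, A: np.ndarray,
                training: bool = False, rng: np.random.Generator | None = None) -> dict:
        """Full pass; returns probabilities plus pooling diagnostics.

        Output dict: ``probs`` (B, n_classes) Tensor, ``node_gates`` (B, n)
        per-node attention gate values, ``kept_idx`` (B, kept) or None.
        """
        cfg = self.config
        E = _zero_diagonal(E)
        history = self.encode(X, E, return_history=True)
        n = X.shape[1]
        scale = 1.0 / math.sqrt(max(n - 1, 1))
        strengths = E.sum(axis=2) * scale  # (B, n, m) per-window node strength
        strengths = strengths - strengths.mean(axis=1, keepdims=True)
        h = self.temporal_pattern(history, strengths)
        if cfg.pooling_ratio is not None:
            xp, _, idx, _, gates = _pool_core(
                h, A, cfg.pooling_ratio,
                self.params["pool_ws"], self.params["pool_wn"], cfg.pool_gate,
            )
            node_gates = gates.data[..., 0]
        else:
            xp, idx, node_gates = h, None, np.ones(h.data.shape[:2])
        emb = readout(xp)
        probs = classify(emb, self.params, cfg.dropout_p, training, rng)
        return {"probs": probs, "node_gates": node_gates, "kept_idx": idx}

    def loss(self, probs: Tensor, y: np.ndarray) -> Tensor:
        """Mean cross-entropy of the softmax output against integer labels."""
        y = np.asarray(y, dtype=int)
        onehot = np.eye(self.config.n_classes)[y]
        return (probs.log() * onehot).sum() * (-1.0 / len(y))


def grnn_forward(graph, params_or_model, config: ModelConfig | None = None):
    """Encode one subject's dynamic graph; returns final node states (n, H).

    Accepts either a DynamicGRNN or a (params dict, config) pair via the
    model. Convenience wrapper around the batched encoder.
    """
    if isinstance(params_or_model, DynamicGRNN):
        model = params_or_model
    else:
        if config is None:
            raise ConfigError("config required when passing a parameter dict")
        model = DynamicGRNN(config)
        model.set_params({k: np.asarray(v.data if isinstance(v, Tensor) else v)
                          for k, v in params_or_model.items()})
    X = graph.node_features[None]
    E = graph.edge_features[None]
    return model.encode(X, E).data[0]
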