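"""The graph-interaction sequence model for disorder and disordered functions.

Architecture, per residue i of a protein of length L:

1. a bidirectional GRU over the per-residue embeddings r_1..r_L yields
   contextual encodings P = [p_1..p_L];
2. a unidirectional GRU with global dot-product attention
   (s_ij = h_{i-1}^T W_a p_j, alpha_ij = softmax_j, c_i = sum_j alpha_ij p_j,
   h_i = GRU(h_{i-1}, c_i)) yields a hidden representation h_i;
3. six fully connected mapping layers produce function node features
   X_i^(n) = ReLU(h_i W^(n) + b^(n));
4. a fully connected 6-node functional graph with a trainable adjacency A
   (off-diagonals initialized from the pairwise information-gain matrix,
   diagonal self-loops initialized to 1) is aggregated by a GCN:
   Y_i^(n) = ReLU(sum_m A_nm (X_i^(m) W'^(n)) + b'^(n));
5. the disorder feature Y_i^IDR is the elementwise max over the six
   aggregated node features;
6. seven sigmoid heads emit propensities: disorder from Y^IDR, each function
   n from Y^(n).

The sequence-only ablation variant removes steps 4-5 and reads the heads
directly from the mapped node features (max-pooled for disorder).

All tensors run on the in-package numpy autograd engine; the same batched
core serves inference (B=1) and training (padded batches with masks).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from ._autograd import Tensor, concat, stack
from .io import EmbeddingMatrix, N_FUNCTIONS, N_LABELS, PropensityProfile

__all__ = [
    "ModelConfig",
    "AttentionState",
    "init_adjacency",
    "init_params",
    "encode_context",
    "attention_weights",
    "attention_gru",
    "map_function_features",
    "gcn_aggregate",
    "disorder_pool",
    "forward",
    "forward_seq_ablation",
    "forward_batch",
    "save_checkpoint",
    "load_checkpoint",
]

PACKAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions and options fully determining every parameter shape.

    ``embed_dim`` is the width D of the input per-residue embeddings
    (1024 for ProtT5-style encoders; anything >= 1 works). Hidden sizes are
    per direction for the Bi-GRU. ``node_feature_dim`` is F, the width of
    each function node's feature vector.
    """

    embed_dim: int = 1024
    bigru_hidden: int = 128
    attn_gru_hidden: int = 128
    node_feature_dim: int = 32
    n_functions: int = 6
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_functions != N_FUNCTIONS:
            raise ValueError(f"n_functions must be {N_FUNCTIONS}")
        for name in ("embed_dim", "bigru_hidden", "attn_gru_hidden",
                     "node_feature_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def context_dim(self) -> int:
        return 2 * self.bigru_hidden


@dataclass
class AttentionState:
    """Trace of the attention GRU: hiddens h_i, weights, scores, contexts."""

    hidden: np.ndarray    # (L, attn_hidden)
    weights: np.ndarray   # (L, L), rows sum to 1
    scores: np.ndarray    # (L, L)
    context: np.ndarray   # (L, context_dim)


# ----------------------------------------------------------------------
# Parameters
# ----------------------------------------------------------------------

_GRU_GATES = ("z", "r", "h")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _init_gru(rng, prefix: str, d_in: int, d_hid: int, params: dict) -> None:
    # input kernels Glorot-uniform, recurrent kernels orthogonal
    for g in _GRU_GATES:
        params[f"{prefix}.W{g}"] = Tensor(_glorot(rng, d_in, d_hid), True)
        params[f"{prefix}.U{g}"] = Tensor(_orthogonal(rng, d_hid), True)
        params[f"{prefix}.b{g}"] = Tensor(np.zeros(d_hid), True)


def init_adjacency(ig: np.ndarray, self_loop: float = 1.0) -> np.ndarray:
    """Adjacency initializer: IG off-diagonals, ``self_loop`` on the diagonal."""
    ig = np.asarray(ig, dtype=np.float64)
    if ig.shape != (N_FUNCTIONS, N_FUNCTIONS):
        raise ValueError(f"IG matrix must be {N_FUNCTIONS}x{N_FUNCTIONS}")
    if not np.isfinite(ig).all():
        raise ValueError("IG matrix contains non-finite entries")
    adj = ig.copy()
    np.fill_diagonal(adj, self_loop)
    return adj


def init_params(
    config: ModelConfig,
    ig: np.ndarray | None = None,
    self_loop: float = 1.0,
) -> dict[str, Tensor]:
    """Create all trainable parameters; adjacency from ``ig`` if given."""
    rng = np.random.default_rng(config.seed)
    C, Ha, F = config.context_dim, config.attn_gru_hidden, config.node_feature_dim
    params: dict[str, Tensor] = {}
    _init_gru(rng, "bigru_fwd", config.embed_dim, config.bigru_hidden, params)
    _init_gru(rng, "bigru_bwd", config.embed_dim, config.bigru_hidden, params)
    params["attn.Wa"] = Tensor(_glorot(rng, Ha, C), True)
    _init_gru(rng, "attn_gru", C, Ha, params)
    params["map.W"] = Tensor(
        np.stack([_glorot(rng, Ha, F) for _ in range(N_FUNCTIONS)]), True)
    params["map.b"] = Tensor(np.zeros((N_FUNCTIONS, F)), True)
    adj = init_adjacency(ig, self_loop) if ig is not None else np.eye(N_FUNCTIONS)
    params["gcn.A"] = Tensor(adj, True)
    params["gcn.W"] = Tensor(
        np.stack([_glorot(rng, F, F) for _ in range(N_FUNCTIONS)]), True)
    params["gcn.b"] = Tensor(np.zeros((N_FUNCTIONS, F)), True)
    params["head.w"] = Tensor(_glorot(rng, N_LABELS, F), True)
    params["head.b"] = Tensor(np.zeros(N_LABELS), True)
    return params


def _check_shapes(params: dict[str, Tensor], config: ModelConfig) -> None:
    if params["bigru_fwd.Wz"].shape != (config.embed_dim, config.bigru_hidden):
        raise ValueError(
            f"embedding dim mismatch: params expect input width "
            f"{params['bigru_fwd.Wz'].shape[0]}, config says {config.embed_dim}"
        )


# ----------------------------------------------------------------------
# Batched forward core
# ----------------------------------------------------------------------

def _gru_step(params, prefix: str, x: Tensor, h: Tensor) -> Tensor:
    p = lambda s: params[f"{prefix}.{s}"]
    z = (x @ p("Wz") + h @ p("Uz") + p("bz")).sigmoid()
    r = (x @ p("Wr") + h @ p("Ur") + p("br")).sigmoid()
    hh = (x @ p("Wh") + (r * h) @ p("Uh") + p("bh")).tanh()
    return (1.0 - z) * h + z * hh


def _gru_scan(params, prefix, xs: list[Tensor], mask: np.ndarray,
              d_hid: int) -> list[Tensor]:
    """Run a GRU over a list of (B, d_in) steps with per-step masking.

    Masked (padded) steps leave the hidden state unchanged, so reversed-time
    scans over front-padded batches start from the true last residue.
    """
    B = xs[0].shape[0]
    h = Tensor(np.zeros((B, d_hid)))
    out = []
    for t, x in enumerate(xs):
        m = mask[:, t:t + 1]
        h_new = _gru_step(params, prefix, x, h)
        h = m * h_new + (1.0 - m) * h if (m != 1.0).any() else h_new
        out.append(h)
    return out


def forward_batch(
    X: np.ndarray,
    mask: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
    ablation: bool = False,
    collect_traces: bool = False,
    dropout_rng: np.random.Generator | None = None,
):
    """Batched forward pass.

    Parameters
    ----------
    X : (B, L, D) padded embedding batch.
    mask : (B, L) 1.0 for real residues, 0.0 for padding.
    ablation : skip the graph unit; heads read mapped features directly.
    collect_traces : also return numpy traces (attention, node features,
        aggregated features, pooling argmax, logits) for attribution.
    dropout_rng : when given and ``config.dropout`` > 0, applies inverted
        dropout to the attention-GRU hiddens (training only).

    Returns
    -------
    (scores, logits, traces) : scores and logits are (B, L, 7) tensors.
    """
    _check_shapes(params, config)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (B, L, D)")
    if X.shape[2] != config.embed_dim:
        raise ValueError(
            f"embedding dim {X.shape[2]} != config.embed_dim {config.embed_dim}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite embedding values")
    B, L, _ = X.shape
    mask = np.asarray(mask, dtype=np.float64)

    # --- Bi-GRU context encoder ---
    xs = [Tensor(X[:, t, :]) for t in range(L)]
    fwd = _gru_scan(params, "bigru_fwd", xs, mask, config.bigru_hidden)
    xs_rev = xs[::-1]
    mask_rev = mask[:, ::-1]
    bwd = _gru_scan(params, "bigru_bwd", xs_rev, mask_rev, config.bigru_hidden)
    bwd = bwd[::-1]
    p_steps = [concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]  # (B, C) each
    P = stack(p_steps, axis=1)                                     # (B, L, C)
    P_T = P.swapaxes(1, 2)                                         # (B, C, L)

    # --- attention GRU ---
    Ha = config.attn_gru_hidden
    neg = (mask - 1.0) * 1e9   # -1e9 at padded positions
    h = Tensor(np.zeros((B, Ha)))
    hs, alphas, scores_tr, ctxs = [], [], [], []
    for i in range(L):
        s = ((h @ params["attn.Wa"]).reshape(B, 1, config.context_dim) @ P_T)
        s = s.reshape(B, L) + neg
        smax = s.data.max(axis=1, keepdims=True)   # constant shift for stability
        e = (s - smax).exp() * mask
        alpha = e / e.sum(axis=1, keepdims=True)   # (B, L)
        c = (alpha.reshape(B, 1, L) @ P).reshape(B, config.context_dim)
        h_new = _gru_step(params, "attn_gru", c, h)
        m = mask[:, i:i + 1]
        h = m * h_new + (1.0 - m) * h if (m != 1.0).any() else h_new
        hs.append(h)
        if collect_traces:
            alphas.append(alpha.data.copy())
            scores_tr.append(s.data.copy())
            ctxs.append(c.data.copy())
    H = stack(hs, axis=1)                                          # (B, L, Ha)

    if dropout_rng is not None and config.dropout > 0.0:
        keep = 1.0 - config.dropout
        dmask = (dropout_rng.random(H.shape) < keep) / keep
        H = H * dmask

    # --- function feature mapping ---
    Xn = [(H @ params["map.W"][n] + params["map.b"][n]).relu()
          for n in range(N_FUNCTIONS)]                              # (B, L, F)

    # --- graph aggregation ---
    if ablation:
        Yn = Xn
        pooled = stack(Xn, axis=2).max(axis=2)                     # (B, L, F)
    else:
        A = params["gcn.A"]
        Yn = []
        for n in range(N_FUNCTIONS):
            msg = None
            Wn = params["gcn.W"][n]
            for m in range(N_FUNCTIONS):
                term = A[n, m] * (Xn[m] @ Wn)
                msg = term if msg is None else msg + term
            Yn.append((msg + params["gcn.b"][n]).relu())
        pooled = stack(Yn, axis=2).max(axis=2)                     # Y^IDR

    # --- output heads ---
    F = config.node_feature_dim
    w, b = params["head.w"], params["head.b"]
    logits = [pooled @ w[0].reshape(F, 1) + b[0]]
    for n in range(N_FUNCTIONS):
        logits.append(Yn[n] @ w[n + 1].reshape(F, 1) + b[n + 1])
    logits = concat(logits, axis=-1)                               # (B, L, 7)
    scores = logits.sigmoid()

    traces: dict[str, Any] = {}
    if collect_traces:
        Ys = np.stack([y.data for y in Yn], axis=2)                # (B, L, 6, F)
        traces = {
            "P": P.data.copy(),
            "attn_weights": np.stack(alphas, axis=1),              # (B, L, L)
            "attn_scores": np.stack(scores_tr, axis=1),
            "attn_context": np.stack(ctxs, axis=1),
            "H": H.data.copy(),
            "X_nodes": np.stack([x.data for x in Xn], axis=2),     # (B, L, 6, F)
            "Y_nodes": Ys,
            "Y_idr": pooled.data.copy(),
            "pool_argmax": Ys.argmax(axis=2),                      # (B, L, F)
            "logits": logits.data.copy(),
            "ablation": ablation,
        }
    return scores, logits, traces


# ----------------------------------------------------------------------
# Per-protein operations (numpy in / numpy out)
# ----------------------------------------------------------------------

def _ones_mask(L: int) -> np.ndarray:
    return np.ones((1, L))


def encode_context(emb: EmbeddingMatrix, params, config: ModelConfig) -> np.ndarray:
    """Bi-GRU contextual encodings P, shape (L, 2*bigru_hidden)."""
    _check_shapes(params, config)
    X = emb.vectors[None, :, :]
    L = emb.length
    xs = [Tensor(X[:, t, :]) for t in range(L)]
    mask = _ones_mask(L)
    fwd = _gru_scan(params, "bigru_fwd", xs, mask, config.bigru_hidden)
    bwd = _gru_scan(params, "bigru_bwd", xs[::-1], mask, config.bigru_hidden)[::-1]
    return np.concatenate(
        [np.stack([f.data[0] for f in fwd]), np.stack([b.data[0] for b in bwd])],
        axis=1,
    )


def attention_weights(
    h_prev: np.ndarray, P: np.ndarray, Wa: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One attention row: scores s_j = h_prev^T Wa p_j and their softmax."""
    scores = (h_prev @ np.asarray(Wa)) @ np.asarray(P).T
    if not np.isfinite(scores).all():
        raise ValueError("non-finite attention scores")
    e = np.exp(scores - scores.max())
    return scores, e / e.sum()


def attention_gru(P: np.ndarray, params, config: ModelConfig) -> AttentionState:
    """Run the attention GRU over encodings P (L, C); h_0 = 0."""
    L = P.shape[0]
    Ha = config.attn_gru_hidden
    h = np.zeros(Ha)
    hidden, weights, scores, contexts = [], [], [], []
    for _ in range(L):
        s, alpha = attention_weights(h, P, params["attn.Wa"].data)
        c = alpha @ P
        ht = _gru_step(params, "attn_gru",
                       Tensor(c[None, :]), Tensor(h[None, :])).data[0]
        h = ht
        hidden.append(ht)
        weights.append(alpha)
        scores.append(s)
        contexts.append(c)
    return AttentionState(
        np.stack(hidden), np.stack(weights), np.stack(scores), np.stack(contexts)
    )


def map_function_features(h: np.ndarray, params) -> np.ndarray:
    """Six mapped node features X^(n) = ReLU(h W^(n) + b^(n)), shape (6, F)."""
    h = np.asarray(h)
    W, b = params["map.W"].data, params["map.b"].data
    return np.maximum(np.einsum("h,nhf->nf", h, W) + b, 0.0)


def gcn_aggregate(node_features: np.ndarray, params) -> np.ndarray:
    """GCN step on one residue's (6, F) node features -> aggregated (6, F)."""
    Xn = np.asarray(node_features, dtype=np.float64)
    A = params["gcn.A"].data
    W, b = params["gcn.W"].data, params["gcn.b"].data
    out = np.empty_like(Xn)
    for n in range(N_FUNCTIONS):
        acc = np.zeros(Xn.shape[1])
        for m in range(N_FUNCTIONS):
            acc = acc + A[n, m] * (Xn[m] @ W[n])
        out[n] = np.maximum(acc + b[n], 0.0)
    return out


def disorder_pool(aggregated: np.ndarray) -> np.ndarray:
    """Elementwise max over the six nodes for each feature dimension."""
    return np.asarray(aggregated).max(axis=0)


def forward(
    emb: EmbeddingMatrix,
    params,
    config: ModelConfig,
    return_traces: bool = False,
):
    """Inference on one protein: L x 7 propensity profile (dropout off)."""
    scores, _, traces = forward_batch(
        emb.vectors[None], _ones_mask(emb.length), params, config,
        collect_traces=return_traces,
    )
    profile = PropensityProfile(emb.protein_id, scores.data[0])
    if return_traces:
        return profile, {k: (v[0] if isinstance(v, np.ndarray) else v)
                         for k, v in traces.items()}
    return profile


def forward_seq_ablation(emb: EmbeddingMatrix, params, config: ModelConfig):
    """Sequence-only variant: heads read mapped features, no graph unit."""
    scores, _, _ = forward_batch(
        emb.vectors[None], _ones_mask(emb.length), params, config, ablation=True,
    )
    return PropensityProfile(emb.protein_id, scores.data[0])


# ----------------------------------------------------------------------
# Checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(
    path,
    params: dict[str, Tensor],
    config: ModelConfig,
    thresholds: np.ndarray | None = None,
    ig: np.ndarray | None = None,
) -> None:
    """Single-file checkpoint: parameters + config + thresholds + IG matrix."""
    arrays = {f"param:{k}": v.data for k, v in params.items()}
    meta = {"config": asdict(config), "version": PACKAGE_VERSION}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8).copy()
    if thresholds is not None:
        arrays["__thresholds__"] = np.asarray(thresholds, dtype=np.float64)
    if ig is not None:
        arrays["__ig__"] = np.asarray(ig, dtype=np.float64)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint -> (params, config, thresholds, ig)."""
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:  # corrupted or wrong format
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    if "__meta__" not in arrays:
        raise ValueError(f"checkpoint {path} missing metadata")
    meta = json.loads(bytes(arrays["__meta__"]).decode())
    config = ModelConfig(**meta["config"])
    params = {
        k[len("param:"):]: Tensor(v, True)
        for k, v in arrays.items() if k.startswith("param:")
    }
    thresholds = arrays.get("__thresholds__")
    ig = arrays.get("__ig__")
    return params, config, thresholds, ig
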