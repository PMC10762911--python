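"""Layer-wise relevance propagation through the graph-interaction unit.

The alpha-beta rule distributes a head's relevance backwards over a linear
layer's inputs in proportion to signed contributions w_jk * h_j:

    R_j = sum_k ( alpha * z+_jk / (sum_j z+_jk + b+_k)
                - beta  * z-_jk / (sum_j z-_jk + b-_k) ) * R_k

with alpha - beta = 1. Relevance is seeded with the head's pre-sigmoid
logit, propagated through the output head and the GCN layer, and stops at
the six mapped node features X^(n). The contribution score of a node is the
sum of relevance over its features; the contribution of an edge is the sum
of the two node scores it links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .io import LABELS, N_FUNCTIONS, N_LABELS, LabelMatrix, PropensityProfile

logger = logging.getLogger("disograph")

__all__ = [
    "LRPConfig",
    "RelevanceMap",
    "EDGE_PAIRS",
    "lrp_linear",
    "explain_residue",
    "aggregate_importance",
]

#: unordered node pairs in fixed order; edge_scores vectors follow this
EDGE_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(N_FUNCTIONS), 2))

_STAB = 1e-9


@dataclass(frozen=True)
class LRPConfig:
    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            raise ValueError("conservation requires alpha - beta == 1")


@dataclass
class RelevanceMap:
    """Node/edge contributions for one (protein, residue, head) query."""

    protein_id: str
    residue: int              # 0-based residue index
    head: int                 # 0 = disorder, 1..6 = functions
    node_scores: np.ndarray   # (6,)
    edge_scores: np.ndarray   # (15,), ordered as EDGE_PAIRS
    layer_traces: list[np.ndarray] = field(default_factory=list)


def lrp_linear(
    relevance_out: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    activations_in: np.ndarray,
    config: LRPConfig = LRPConfig(),
) -> np.ndarray:
    """Propagate relevance through y = activations_in @ weights + bias.

    ``weights`` is (J, K); contributions are separated by the sign of
    w_jk * h_j; denominators get a sign-matched 1e-9 stabilizer.
    """
    h = np.asarray(activations_in, dtype=np.float64)
    W = np.asarray(weights, dtype=np.float64)
    R = np.asarray(relevance_out, dtype=np.float64)
    b = np.zeros(W.shape[1]) if bias is None else np.asarray(bias, np.float64)
    z = W * h[:, None]                       # (J, K)
    zp = np.clip(z, 0.0, None)
    zn = np.clip(z, None, 0.0)
    denom_p = zp.sum(axis=0) + np.clip(b, 0.0, None) + _STAB
    denom_n = zn.sum(axis=0) + np.clip(b, None, 0.0) - _STAB
    frac = config.alpha * zp / denom_p - config.beta * zn / denom_n
    return frac @ R


def _route_pool(relevance: np.ndarray, argmax: np.ndarray) -> np.ndarray:
    """Distribute max-pool relevance (F,) to the winning node per dimension."""
    out = np.zeros((N_FUNCTIONS, relevance.shape[0]))
    out[argmax, np.arange(relevance.shape[0])] = relevance
    return out


def explain_residue(
    traces: dict,
    params,
    residue: int,
    head: int,
    config: LRPConfig = LRPConfig(),
    protein_id: str = "",
) -> RelevanceMap:
    """LRP for one residue and one head down to the mapped node features.

    ``traces`` must come from ``forward(..., return_traces=True)``. The
    relevance seed is the head's pre-sigmoid logit. For the disorder head the
    max-pool routes relevance to the per-dimension winning node first.
    """
    required = {"X_nodes", "Y_nodes", "Y_idr", "pool_argmax", "logits"}
    if not required.issubset(traces):
        raise ValueError(
            "traces are missing graph-unit arrays; rerun forward() with "
            "return_traces=True")
    if traces.get("ablation"):
        raise ValueError("cannot explain the graph unit of an ablation run")
    if not 0 <= head < N_LABELS:
        raise ValueError(f"head must be in [0, {N_LABELS})")
    X = traces["X_nodes"][residue]          # (6, F)
    Y = traces["Y_nodes"][residue]          # (6, F)
    F = X.shape[1]
    w_head = params["head.w"].data
    b_head = params["head.b"].data
    A = params["gcn.A"].data
    Wg = params["gcn.W"].data
    bg = params["gcn.b"].data
    seed = np.array([traces["logits"][residue, head]])
    layer_traces = [seed.copy()]

    if head == 0:
        r_idr = lrp_linear(seed, w_head[0].reshape(F, 1),
                           b_head[0:1], traces["Y_idr"][residue], config)
        layer_traces.append(r_idr.copy())
        per_node = _route_pool(r_idr, traces["pool_argmax"][residue])
        layer_traces.append(per_node.copy())
        node_targets = [(n, per_node[n]) for n in range(N_FUNCTIONS)
                        if np.any(per_node[n])]
    else:
        n = head - 1
        r_y = lrp_linear(seed, w_head[head].reshape(F, 1),
                         b_head[head:head + 1], Y[n], config)
        layer_traces.append(r_y.copy())
        node_targets = [(n, r_y)]

    # through the GCN layer of each target node: inputs are the concatenated
    # six node features, with effective weight block m = A[n, m] * W'^(n)
    r_x = np.zeros(N_FUNCTIONS * F)
    x_cat = X.reshape(-1)
    for n, r_y in node_targets:
        W_eff = np.concatenate([A[n, m] * Wg[n] for m in range(N_FUNCTIONS)],
                               axis=0)                      # (6F, F)
        r_x += lrp_linear(r_y, W_eff, bg[n], x_cat, config)
    layer_traces.append(r_x.copy())

    node_scores = r_x.reshape(N_FUNCTIONS, F).sum(axis=1)
    edge_scores = np.array([node_scores[a] + node_scores[b]
                            for a, b in EDGE_PAIRS])
    return RelevanceMap(protein_id, residue, head, node_scores, edge_scores,
                        layer_traces)


def aggregate_importance(
    maps: Sequence[RelevanceMap],
    predictions: Sequence[PropensityProfile],
    labels: Sequence[LabelMatrix],
    thresholds,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sum node/edge scores over true-positive residues, per explained head.

    A residue counts for a head when its true label is 1 and its propensity
    is >= the head's threshold. Heads with no true positives report zero
    vectors with a warning.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    pred_by_id = {p.protein_id: p for p in predictions}
    lab_by_id = {l.protein_id: l for l in labels}
    sums: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    seen_heads: set[int] = set()
    for m in maps:
        seen_heads.add(m.head)
        pred = pred_by_id[m.protein_id]
        lab = lab_by_id[m.protein_id]
        is_tp = (lab.labels[m.residue, m.head] == 1 and
                 pred.scores[m.residue, m.head] >= thresholds[m.head])
        if not is_tp:
            continue
        node, edge = sums.setdefault(
            m.head, (np.zeros(N_FUNCTIONS), np.zeros(len(EDGE_PAIRS))))
        node += m.node_scores
        edge += m.edge_scores
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for head in sorted(seen_heads):
        if head not in sums:
            logger.warning("head %s has no true positives; zero aggregate",
                           LABELS[head])
            sums[head] = (np.zeros(N_FUNCTIONS), np.zeros(len(EDGE_PAIRS)))
        out[LABELS[head]] = sums[head]
    return out
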