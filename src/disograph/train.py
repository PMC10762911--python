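"""Joint multi-head training and per-head threshold calibration.

The loss is the mean over the seven heads of the per-head binary
cross-entropy, each averaged over unmasked residues (natural log). Model
selection keeps the parameters with minimum validation loss, not the final
epoch. Variable-length proteins are batched by padding with an all-masked
tail; masked residues never contribute to loss or metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autograd import Tensor, backward
from .io import EmbeddingMatrix, LabelMatrix, N_LABELS, PropensityProfile
from .model import ModelConfig, forward_batch, init_params

logger = logging.getLogger("disograph")

__all__ = [
    "TrainConfig",
    "ThresholdSet",
    "joint_bce_loss",
    "train",
    "calibrate_thresholds",
]

EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8          # proteins per optimizer step
    max_epochs: int = 200
    patience: int = 20           # early stop on stalled validation loss
    seed: int = 0
    optimizer: str = "adam"
    lr_schedule: str = "cosine"   # "cosine" decay to ~0 or "constant"
    grad_clip: float = 5.0        # global gradient-norm ceiling; 0 disables
    head_weights: tuple = (1.0,) * N_LABELS

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("rates and counts must be positive")
        if len(self.head_weights) != N_LABELS:
            raise ValueError(f"head_weights must have {N_LABELS} entries")


@dataclass
class ThresholdSet:
    """Seven per-head decision thresholds plus the calibration method tag."""

    values: np.ndarray
    method: str = "max_f1"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_LABELS,):
            raise ValueError(f"need {N_LABELS} thresholds")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("thresholds must lie in [0, 1]")


def joint_bce_loss(
    profile: PropensityProfile,
    labels: LabelMatrix,
    mask: np.ndarray | None = None,
) -> float:
    """Mean over 7 heads of per-head BCE averaged over unmasked residues.

    Scores are clipped to [eps, 1-eps] with eps = 1e-7; the result is in
    nats and is ~0 iff predictions match the labels up to clipping.
    """
    y = labels.labels.astype(np.float64)
    s = profile.scores
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch: scores {s.shape} vs labels {y.shape}")
    s = np.clip(s, EPS, 1.0 - EPS)
    if mask is None:
        mask = np.ones(s.shape[0])
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim == 1:
        mask = mask[:, None] * np.ones((1, N_LABELS))
    per_elem = -(y * np.log(s) + (1.0 - y) * np.log(1.0 - s))
    denom = mask.sum(axis=0)
    denom[denom == 0] = 1.0
    per_head = (per_elem * mask).sum(axis=0) / denom
    return float(per_head.mean())


# ----------------------------------------------------------------------
# Optimizer
# ----------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# ----------------------------------------------------------------------
# Training loop
# ----------------------------------------------------------------------

def _pad_batch(items: Sequence[tuple[EmbeddingMatrix, LabelMatrix]]):
    B = len(items)
    L = max(e.length for e, _ in items)
    D = items[0][0].dim
    X = np.zeros((B, L, D))
    Y = np.zeros((B, L, N_LABELS))
    mask = np.zeros((B, L))
    for i, (emb, lab) in enumerate(items):
        X[i, :emb.length] = emb.vectors
        Y[i, :lab.length] = lab.labels
        mask[i, :emb.length] = 1.0
    return X, Y, mask


def _batch_loss(X, Y, mask, params, config, head_weights,
                dropout_rng=None) -> Tensor:
    """Masked multi-head BCE on logits (numerically stable)."""
    _, logits, _ = forward_batch(X, mask, params, config,
                                 dropout_rng=dropout_rng)
    # bce = softplus(z) - y*z, elementwise; mask padded residues
    bce = logits.softplus() - Tensor(Y) * logits
    m3 = mask[:, :, None] * np.ones((1, 1, N_LABELS))
    denom = m3.sum(axis=(0, 1))
    per_head = (bce * m3).sum(axis=0).sum(axis=0) / denom
    w = np.asarray(head_weights, dtype=np.float64)
    return (per_head * (w / w.sum())).sum()


def _eval_loss(data, params, config, head_weights) -> float:
    X, Y, mask = _pad_batch(data)
    loss = _batch_loss(X, Y, mask, params, config, head_weights)
    return float(loss.data)


def train(
    dataset: Sequence[tuple[EmbeddingMatrix, LabelMatrix]],
    val: Sequence[tuple[EmbeddingMatrix, LabelMatrix]],
    tconfig: TrainConfig,
    mconfig: ModelConfig,
    ig: np.ndarray | None = None,
    params: dict[str, Tensor] | None = None,
):
    """Train the model; returns (best params, thresholds, history).

    The adjacency is initialized from the training set's IG matrix (when
    ``ig`` is given) before the first step. The returned parameters are those
    achieving the minimum validation loss. Thresholds are calibrated on the
    validation set at the best parameters. Fully reproducible given the seeds
    in ``tconfig`` and ``mconfig``.
    """
    if not dataset or not val:
        raise ValueError("train and validation sets must be non-empty")
    if params is None:
        params = init_params(mconfig, ig=ig)
    rng = np.random.default_rng(tconfig.seed)
    opt = _Adam(params, tconfig.learning_rate)
    history: list[dict] = []
    # epoch 0: the untrained model, the baseline for loss-reduction curves
    best_val = _eval_loss(val, params, mconfig, tconfig.head_weights)
    history.append({
        "epoch": 0,
        "train_loss": _eval_loss(dataset, params, mconfig,
                                 tconfig.head_weights),
        "val_loss": best_val,
    })
    best_params = {k: p.data.copy() for k, p in params.items()}
    best_epoch = 0
    order = np.arange(len(dataset))
    for epoch in range(1, tconfig.max_epochs + 1):
        if tconfig.lr_schedule == "cosine":
            opt.lr = tconfig.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * (epoch - 1) / tconfig.max_epochs))
        rng.shuffle(order)
        train_losses = []
        for start in range(0, len(order), tconfig.batch_size):
            batch = [dataset[i] for i in order[start:start + tconfig.batch_size]]
            X, Y, mask = _pad_batch(batch)
            drop_rng = (np.random.default_rng(rng.integers(2 ** 31))
                        if mconfig.dropout > 0 else None)
            loss = _batch_loss(X, Y, mask, params, mconfig, tconfig.head_weights,
                               dropout_rng=drop_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"divergent loss at epoch {epoch}")
            opt.zero_grad()
            backward(loss)
            if tconfig.grad_clip > 0:
                total = np.sqrt(sum((p.grad ** 2).sum()
                                    for p in params.values()
                                    if p.grad is not None))
                if total > tconfig.grad_clip:
                    scale = tconfig.grad_clip / total
                    for p in params.values():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            train_losses.append(float(loss.data))
        val_loss = _eval_loss(val, params, mconfig, tconfig.head_weights)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"divergent validation loss at epoch {epoch}")
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss,
        })
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: p.data.copy() for k, p in params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= tconfig.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    for k in params:
        params[k].data = best_params[k]
        params[k].grad = None
    # calibrate thresholds on the validation set at the selected parameters
    profiles, labs = [], []
    for emb, lab in val:
        scores, _, _ = forward_batch(
            emb.vectors[None], np.ones((1, emb.length)), params, mconfig)
        profiles.append(PropensityProfile(emb.protein_id, scores.data[0]))
        labs.append(lab)
    thresholds = calibrate_thresholds(profiles, labs)
    return params, thresholds, history


# ----------------------------------------------------------------------
# Threshold calibration
# ----------------------------------------------------------------------

def _f1_at(scores: np.ndarray, labels: np.ndarray, thr: float) -> float:
    pred = scores >= thr
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def max_f1_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(threshold, F1) maximizing F1 over observed scores; ties -> larger thr."""
    best_thr, best_f1 = 0.5, -1.0
    for thr in np.unique(scores):
        f1 = _f1_at(scores, labels, float(thr))
        if f1 > best_f1 or (f1 == best_f1 and thr > best_thr):
            best_f1, best_thr = f1, float(thr)
    return best_thr, best_f1


def calibrate_thresholds(
    profiles: Sequence[PropensityProfile],
    labels: Sequence[LabelMatrix],
) -> ThresholdSet:
    """Per-head max-F1 thresholds over pooled residues.

    A head with no positives (or no negatives) defaults to 0.5 with a
    warning.
    """
    if not profiles:
        raise ValueError("no profiles given")
    S = np.concatenate([p.scores for p in profiles], axis=0)
    Y = np.concatenate([l.labels for l in labels], axis=0)
    if S.shape != Y.shape:
        raise ValueError("profiles and labels disagree in shape")
    out = np.full(N_LABELS, 0.5)
    for head in range(N_LABELS):
        y = Y[:, head]
        if y.min() == y.max():
            logger.warning(
                "head %d has a single class; threshold defaults to 0.5", head)
            continue
        out[head], _ = max_f1_threshold(S[:, head], y)
    return ThresholdSet(out)
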