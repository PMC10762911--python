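"""CAID-style evaluation metrics for per-residue propensity predictions.

Threshold-independent: AUC (Mann-Whitney, ties 1/2), AUPR (trapezoidal area
under the precision-recall curve), APS (step-wise average precision), Fmax
(maximum F1 over observed score thresholds). Binary: MCC and balanced
accuracy, with degenerate denominators mapped to 0. Residues are pooled
across proteins per head for dataset-level reports; per-protein mode
averages over proteins with both classes present.

Multifunctional (MF) residues — residues carrying two or more true function
labels — are evaluated jointly: a residue of an MF type is correctly
predicted only if every function of the type is predicted positive, and the
type-level score is the minimum of the involved heads' propensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, \
    roc_auc_score

from .io import LABELS, N_LABELS, LabelMatrix, PropensityProfile
from .train import max_f1_threshold

logger = logging.getLogger("disograph")

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "auc",
    "aupr_aps",
    "fmax",
    "mcc_bacc",
    "confusion",
    "evaluate",
    "mf_residue_eval",
    "compare_predictors",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Per-head metric table; optional per-protein breakdown."""

    per_head: dict[str, dict[str, float]]
    per_protein: dict[str, dict[str, dict[str, float]]] | None = None

    def to_tsv(self) -> str:
        cols = ["auc", "aupr", "aps", "fmax", "mcc", "bacc", "threshold"]
        lines = ["head\t" + "\t".join(cols)]
        for head, vals in self.per_head.items():
            lines.append(head + "\t" + "\t".join(
                "na" if vals.get(c) is None else f"{vals[c]:.4f}" for c in cols))
        return "\n".join(lines) + "\n"


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC = P(random positive outscores random negative), ties 1/2."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks; used in the bootstrap inner loop."""
    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return (r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def aupr_aps(scores, labels) -> tuple[float, float]:
    """(AUPR, APS): trapezoidal PR area and step-wise average precision."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined without positives")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns recall decreasing; integrate over recall
    aupr = float(np.trapezoid(precision[::-1], recall[::-1]))
    aps = float(average_precision_score(labels, scores))
    return aupr, aps


def fmax(scores, labels) -> tuple[float, float]:
    """(Fmax, threshold): max F1 over observed scores; ties -> larger thr."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.sum() == 0:
        raise ValueError("Fmax undefined without positives")
    thr, f1 = max_f1_threshold(scores, labels)
    return f1, thr


def mcc_bacc(counts: ConfusionCounts) -> tuple[float, float]:
    """Matthews correlation and balanced accuracy, degenerate cases -> 0 / 0.5
    conventions: MCC = 0 when any denominator factor is 0; a missing class
    contributes rate 0 to BACC's average."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    return float(mcc), float((tpr + tnr) / 2.0)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the >= threshold binarization rule."""
    labels = _check_binary(labels)
    pred = np.asarray(scores, dtype=np.float64) >= threshold
    return ConfusionCounts(
        tp=int((pred & (labels == 1)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
    )


def _head_metrics(scores, labels, threshold: float) -> dict[str, float]:
    out: dict[str, float] = {"threshold": threshold}
    both = labels.min() != labels.max()
    out["auc"] = auc(scores, labels) if both else None
    if labels.sum() > 0:
        out["aupr"], out["aps"] = aupr_aps(scores, labels)
        out["fmax"], _ = fmax(scores, labels)
    else:
        out["aupr"] = out["aps"] = out["fmax"] = None
    out["mcc"], out["bacc"] = mcc_bacc(confusion(scores, labels, threshold))
    return out


def _pool(predictions, labels):
    by_id = {l.protein_id: l for l in labels}
    S, Y = [], []
    for p in predictions:
        if p.protein_id not in by_id:
            raise ValueError(f"no labels for protein {p.protein_id!r}")
        lab = by_id[p.protein_id]
        if lab.length != p.length:
            raise ValueError(f"length mismatch for protein {p.protein_id!r}")
        S.append(p.scores)
        Y.append(lab.labels)
    return np.concatenate(S), np.concatenate(Y)


def evaluate(
    predictions: Sequence[PropensityProfile],
    labels: Sequence[LabelMatrix],
    thresholds,
    per_protein: bool = False,
) -> MetricReport:
    """Dataset-level metrics with residues pooled per head.

    ``per_protein=True`` additionally computes each metric within every
    protein; the per-head averages cover proteins where the head has both
    classes.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    S, Y = _pool(predictions, labels)
    per_head = {
        LABELS[h]: _head_metrics(S[:, h], Y[:, h], float(thresholds[h]))
        for h in range(N_LABELS)
    }
    report = MetricReport(per_head)
    if per_protein:
        by_id = {l.protein_id: l for l in labels}
        table: dict[str, dict[str, dict[str, float]]] = {}
        for p in predictions:
            lab = by_id[p.protein_id]
            table[p.protein_id] = {}
            for h in range(N_LABELS):
                y = lab.labels[:, h]
                if y.min() == y.max():
                    continue   # excluded from per-protein averaging
                table[p.protein_id][LABELS[h]] = _head_metrics(
                    p.scores[:, h], y, float(thresholds[h]))
        report.per_protein = table
    return report


# ----------------------------------------------------------------------
# Multifunctional residues
# ----------------------------------------------------------------------

def mf_residue_eval(
    predictions: Sequence[PropensityProfile],
    labels: Sequence[LabelMatrix],
    thresholds,
) -> dict[tuple[str, ...], dict[str, float]]:
    """Per-MF-type Fmax table over jointly-correct predictions.

    Residues are grouped by their exact set of >= 2 true function labels.
    For each type the binary reduction marks a residue positive iff its
    function set equals the type; the residue's type score is the minimum of
    the involved heads' propensities, so a residue only crosses a threshold
    when every involved head does.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    S, Y = _pool(predictions, labels)
    func_Y = Y[:, 1:]
    types: dict[tuple[int, ...], None] = {}
    per_res_sets = [tuple(np.flatnonzero(row)) for row in func_Y]
    for s in per_res_sets:
        if len(s) >= 2:
            types[s] = None
    out: dict[tuple[str, ...], dict[str, float]] = {}
    if not types:
        logger.warning("no multifunctional residues in the evaluation set")
        return out
    for t in sorted(types):
        heads = [i + 1 for i in t]   # label-matrix columns
        pos = np.array([s == t for s in per_res_sets])
        type_scores = S[:, heads].min(axis=1)
        f1, thr = fmax(type_scores, pos.astype(int))
        bin_thr = (S[:, heads] >= thresholds[heads]).all(axis=1)
        counts = ConfusionCounts(
            tp=int((bin_thr & pos).sum()), fp=int((bin_thr & ~pos).sum()),
            tn=int((~bin_thr & ~pos).sum()), fn=int((~bin_thr & pos).sum()))
        mcc, bacc = mcc_bacc(counts)
        out[tuple(LABELS[h] for h in heads)] = {
            "n_residues": int(pos.sum()),
            "fmax": f1,
            "fmax_threshold": thr,
            "mcc": mcc,
            "bacc": bacc,
        }
    return out


# ----------------------------------------------------------------------
# Predictor comparison
# ----------------------------------------------------------------------

def compare_predictors(
    preds_a: Sequence[PropensityProfile],
    preds_b: Sequence[PropensityProfile],
    labels: Sequence[LabelMatrix],
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Paired bootstrap (resample unit: protein) of the per-head AUC gap.

    Returns a two-sided p-value per head for the null of equal AUC.
    """
    if len(preds_a) < 2:
        raise ValueError("need at least 2 proteins for a paired bootstrap")
    ids = [p.protein_id for p in preds_a]
    if [p.protein_id for p in preds_b] != ids:
        raise ValueError("predictor outputs must cover the same proteins")
    by_id = {l.protein_id: l for l in labels}
    labs = [by_id[i] for i in ids]
    rng = np.random.default_rng(seed)
    n = len(ids)
    pvals: dict[str, float] = {}
    for h in range(N_LABELS):
        ge = le = valid = 0
        for _ in range(n_resamples):
            idx = rng.integers(0, n, size=n)
            y = np.concatenate([labs[i].labels[:, h] for i in idx])
            if y.min() == y.max():
                continue
            sa = np.concatenate([preds_a[i].scores[:, h] for i in idx])
            sb = np.concatenate([preds_b[i].scores[:, h] for i in idx])
            diff = _rank_auc(sa, y) - _rank_auc(sb, y)
            valid += 1
            ge += diff >= 0
            le += diff <= 0
        if valid == 0:
            pvals[LABELS[h]] = float("nan")
            continue
        pvals[LABELS[h]] = min(1.0, 2.0 * min(ge / valid, le / valid))
    return pvals
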