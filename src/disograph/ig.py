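"""Shannon entropy and pairwise information gain over the six function labels.

The correlation between two disordered functions X and Y is quantified as the
reduction in entropy obtained by predicting them jointly rather than
separately,

    IG(X, Y) = H(X) + H(Y) - H(X, Y),

i.e. the mutual information of the two binary per-residue labels, in bits.
Probabilities are pooled empirical frequencies over all residues of all
training proteins (the disorder column is excluded; IG is defined over the six
functions only). The 6 x 6 IG matrix initializes the functional-graph
adjacency; its diagonal stores the per-label entropy H(X).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import FUNCTION_LABELS, N_FUNCTIONS, LabelMatrix

__all__ = [
    "LabelDistribution",
    "entropy",
    "estimate_distribution",
    "information_gain",
    "ig_matrix",
    "write_ig_matrix",
    "read_ig_matrix",
]


@dataclass
class LabelDistribution:
    """Empirical marginals and pairwise 2x2 joints over the function labels."""

    marginal: np.ndarray          # (6,) P(label = 1)
    joint: np.ndarray             # (6, 6, 2, 2); joint[x, y, a, b] = P(X=a, Y=b)
    n_residues: int

    def __post_init__(self):
        for x in range(N_FUNCTIONS):
            for y in range(N_FUNCTIONS):
                if x == y:
                    continue
                tab = self.joint[x, y]
                if abs(tab.sum() - 1.0) > 1e-12:
                    raise ValueError(f"joint table ({x},{y}) does not sum to 1")
                if abs(tab[1].sum() - self.marginal[x]) > 1e-12:
                    raise ValueError(
                        f"joint table ({x},{y}) inconsistent with marginal of {x}"
                    )


def entropy(p: Sequence[float]) -> float:
    """Shannon entropy of a probability vector, in bits; 0*log0 := 0."""
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def estimate_distribution(labels: Sequence[LabelMatrix]) -> LabelDistribution:
    """Pool residues of all proteins and count label (co-)occurrences."""
    if not labels:
        raise ValueError("at least one label matrix required")
    pooled = np.concatenate([lm.labels[:, 1:] for lm in labels], axis=0)
    n = pooled.shape[0]
    if n < 1:
        raise ValueError("no residues in input")
    pooled = pooled.astype(np.float64)
    marginal = pooled.mean(axis=0)
    joint = np.zeros((N_FUNCTIONS, N_FUNCTIONS, 2, 2))
    for x in range(N_FUNCTIONS):
        for y in range(N_FUNCTIONS):
            both = float((pooled[:, x] * pooled[:, y]).mean())
            joint[x, y, 1, 1] = both
            joint[x, y, 1, 0] = marginal[x] - both
            joint[x, y, 0, 1] = marginal[y] - both
            joint[x, y, 0, 0] = 1.0 - marginal[x] - marginal[y] + both
    # clip tiny negatives from float accumulation
    np.clip(joint, 0.0, 1.0, out=joint)
    return LabelDistribution(marginal, joint, n)


def _entropy_unnorm(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def information_gain(dist: LabelDistribution, x: int, y: int) -> float:
    """IG(X, Y) = H(X) + H(Y) - H(X, Y) in bits, clipped to >= 0."""
    if x == y:
        raise ValueError("x and y must differ; use entropy() for the diagonal")
    hx = entropy([1.0 - dist.marginal[x], dist.marginal[x]])
    hy = entropy([1.0 - dist.marginal[y], dist.marginal[y]])
    hxy = _entropy_unnorm(dist.joint[x, y].ravel())
    return max(0.0, hx + hy - hxy)


def ig_matrix(labels: Sequence[LabelMatrix]) -> np.ndarray:
    """The symmetric 6 x 6 IG matrix; diagonal holds per-label entropies."""
    dist = estimate_distribution(labels)
    mat = np.zeros((N_FUNCTIONS, N_FUNCTIONS))
    for x in range(N_FUNCTIONS):
        mat[x, x] = entropy([1.0 - dist.marginal[x], dist.marginal[x]])
        for y in range(x + 1, N_FUNCTIONS):
            v = information_gain(dist, x, y)
            mat[x, y] = mat[y, x] = v
    return mat


def write_ig_matrix(mat: np.ndarray, path) -> None:
    """Serialize as tab-separated 6x6 with a label header (repr precision)."""
    with open(path, "w") as fh:
        fh.write("\t".join(FUNCTION_LABELS) + "\n")
        for row in np.asarray(mat):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_ig_matrix(path) -> np.ndarray:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    if tuple(header) != FUNCTION_LABELS:
        raise ValueError(f"unexpected IG matrix header in {path}")
    mat = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    if mat.shape != (N_FUNCTIONS, N_FUNCTIONS):
        raise ValueError(f"IG matrix in {path} is not 6x6")
    return mat
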