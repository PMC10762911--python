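"""Synthetic datasets: sequences, correlated functional regions, embeddings.

The generator emulates the statistical structure the model exploits:
contiguous per-label functional regions, controllable pairwise label
co-occurrence (hence controllable information gain between labels), a
disorder annotation that is a strict superset of all functional residues,
and per-residue embeddings that carry a recoverable linear signal for each
label (orthonormal per-label signature vectors summed over a residue's
active labels, plus Gaussian noise scaled by 1/SNR).

Amino acids are drawn uniformly: sequence composition deliberately carries
no signal, keeping encoder tests orthogonal to sequence content. Region
lengths are geometric (memoryless). Everything is reproducible from the
mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import (
    FUNCTION_LABELS,
    LABELS,
    N_FUNCTIONS,
    N_LABELS,
    EmbeddingMatrix,
    LabelMatrix,
    ProteinRecord,
    RegionAnnotation,
    build_label_matrix,
)

__all__ = ["SimConfig", "simulate_dataset", "make_signal_embeddings",
           "make_signatures"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    ``region_density`` is the expected fraction of residues covered by each
    function label before co-occurrence spawning; ``cooccurrence[x, y]`` is
    the probability that a placed region of function x spawns an overlapping
    region of function y. ``snr`` scales the Gaussian embedding noise as
    sigma = 1/snr.
    """

    seed: int
    n_proteins: int = 20
    length_range: tuple[int, int] = (40, 80)
    region_density: float = 0.12
    mean_region_length: float = 8.0
    cooccurrence: tuple = tuple(
        tuple(0.0 for _ in range(N_FUNCTIONS)) for _ in range(N_FUNCTIONS))
    disorder_extra_density: float = 0.10
    embed_dim: int = 32
    snr: float = 5.0
    duplicate_labels: tuple[str, str] | None = None

    def __post_init__(self):
        co = np.asarray(self.cooccurrence, dtype=np.float64)
        if co.shape != (N_FUNCTIONS, N_FUNCTIONS):
            raise ValueError("cooccurrence must be 6x6")
        if ((co < 0) | (co > 1)).any():
            raise ValueError("cooccurrence entries must be probabilities")
        if not np.allclose(co, co.T):
            raise ValueError("cooccurrence matrix must be symmetric")
        expected = self.region_density * (1.0 + co.sum(axis=0).max())
        if expected > 1.0:
            raise ValueError(
                f"infeasible densities: expected per-label coverage "
                f"{expected:.2f} > 1")
        if self.embed_dim < N_LABELS:
            raise ValueError(f"embed_dim must be >= {N_LABELS}")
        if not (self.length_range[0] >= 1
                and self.length_range[0] <= self.length_range[1]):
            raise ValueError("invalid length range")


def make_signatures(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Seven mutually orthonormal signature vectors (one per label), (7, D)."""
    if dim < N_LABELS:
        raise ValueError(f"need dim >= {N_LABELS} for orthogonal signatures")
    q, _ = np.linalg.qr(rng.standard_normal((dim, N_LABELS)))
    return q.T


def make_signal_embeddings(
    labels: LabelMatrix,
    config: SimConfig,
    signatures: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> EmbeddingMatrix:
    """Embed residues as the sum of active-label signatures plus noise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if signatures is None:
        signatures = make_signatures(config.embed_dim, rng)
    if signatures.shape != (N_LABELS, config.embed_dim):
        raise ValueError("signatures must be (7, embed_dim)")
    signal = labels.labels.astype(np.float64) @ signatures
    noise = rng.standard_normal(signal.shape) / config.snr
    return EmbeddingMatrix(labels.protein_id, signal + noise,
                           encoder_tag=f"synthetic:snr={config.snr}")


def _sample_regions(
    rng: np.random.Generator, pid: str, L: int, config: SimConfig
) -> list[RegionAnnotation]:
    co = np.asarray(config.cooccurrence, dtype=np.float64)
    mean_len = min(config.mean_region_length, L)
    geom_p = 1.0 / mean_len
    regions: list[RegionAnnotation] = []

    def draw(label: str, near: int | None = None) -> RegionAnnotation:
        length = min(int(rng.geometric(geom_p)), L)
        if near is None:
            start = int(rng.integers(1, L - length + 2))
        else:
            # overlap the spawning region: jitter around its start
            start = int(np.clip(near + rng.integers(-2, 3), 1, L - length + 1))
        return RegionAnnotation(pid, label, start, start + length - 1)

    for x, label in enumerate(FUNCTION_LABELS):
        n_regions = rng.poisson(config.region_density * L / mean_len)
        for _ in range(n_regions):
            base = draw(label)
            regions.append(base)
            for y, other in enumerate(FUNCTION_LABELS):
                if y != x and rng.random() < co[x, y]:
                    regions.append(draw(other, near=base.start))

    if config.duplicate_labels is not None:
        src, dst = config.duplicate_labels
        regions = [r for r in regions if r.label != dst]
        regions += [RegionAnnotation(pid, dst, r.start, r.end)
                    for r in regions if r.label == src]

    # disorder = union of functional regions plus disorder-only segments
    regions += [RegionAnnotation(pid, "disorder", r.start, r.end)
                for r in regions]
    n_dis = rng.poisson(config.disorder_extra_density * L / mean_len)
    for _ in range(n_dis):
        regions.append(draw("disorder"))
    return regions


def simulate_dataset(config: SimConfig):
    """Generate (proteins, regions, label matrices, embeddings).

    Deterministic in ``config.seed``: the same config yields bit-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    signatures = make_signatures(config.embed_dim, rng)
    proteins: list[ProteinRecord] = []
    all_regions: list[RegionAnnotation] = []
    labels: list[LabelMatrix] = []
    embeddings: list[EmbeddingMatrix] = []
    lo, hi = config.length_range
    for i in range(config.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(_AA[j] for j in rng.integers(0, len(_AA), size=L))
        rec = ProteinRecord(f"SYN{i:04d}", seq)
        regions = _sample_regions(rng, rec.id, L, config)
        lab = build_label_matrix(rec, regions)
        emb = make_signal_embeddings(lab, config, signatures=signatures, rng=rng)
        proteins.append(rec)
        all_regions.extend(regions)
        labels.append(lab)
        embeddings.append(emb)
    return proteins, all_regions, labels, embeddings
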