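"""Sequence, annotation, embedding and prediction-file I/O.

Conventions
-----------
* Coordinates in files are 1-based inclusive (DisProt style); internally all
  indexing is 0-based half-open; user-facing output is 1-based again.
* Label columns are fixed everywhere in the package as
  ``[disorder, protein_binding, dna_binding, rna_binding, ion_binding,
  lipid_binding, linker]``.
* Residues not covered by any region of a label are negatives for that label.
* Binarization tie rule: score >= threshold -> positive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("disograph")

#: fixed column order of every L x 7 label/score matrix in the package
LABELS: tuple[str, ...] = (
    "disorder",
    "protein_binding",
    "dna_binding",
    "rna_binding",
    "ion_binding",
    "lipid_binding",
    "linker",
)
#: the six disordered-function labels (disorder excluded), in column order 1..6
FUNCTION_LABELS: tuple[str, ...] = LABELS[1:]
N_LABELS = len(LABELS)
N_FUNCTIONS = len(FUNCTION_LABELS)

#: proteins longer than this are rejected rather than windowed
DEFAULT_MAX_LENGTH = 30000

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """An accession plus an amino-acid sequence (20 canonical letters + X)."""

    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A contiguous functional region, 1-based inclusive coordinates."""

    protein_id: str
    label: str
    start: int
    end: int

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"region {self.protein_id} {self.label}: "
                f"require 1 <= start <= end, got ({self.start}, {self.end})"
            )


@dataclass
class LabelMatrix:
    """L x 7 binary matrix, one column per label in :data:`LABELS` order."""

    protein_id: str
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.shape[1] != N_LABELS:
            raise ValueError(f"label matrix must be L x {N_LABELS}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")
        self.labels = self.labels.astype(np.int8)

    @property
    def length(self) -> int:
        return self.labels.shape[0]


@dataclass
class EmbeddingMatrix:
    """L x D real matrix of per-residue feature vectors."""

    protein_id: str
    vectors: np.ndarray
    encoder_tag: str = "unknown"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (L x D)")
        if not np.isfinite(self.vectors).all():
            raise ValueError(f"embedding for {self.protein_id}: non-finite entries")

    @property
    def length(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class PropensityProfile:
    """L x 7 per-residue propensity scores in [0, 1]."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_LABELS:
            raise ValueError(f"scores must be L x {N_LABELS}")
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            raise ValueError("propensity scores must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------

def read_fasta(path, max_length: int = DEFAULT_MAX_LENGTH) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; non-canonical letters other than X are mapped
    to X with a warning. Duplicate ids and over-long sequences are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(entry.seq).upper()
        cleaned = re.sub("[^ACDEFGHIKLMNPQRSTVWYX]", "X", seq)
        if cleaned != seq:
            logger.warning(
                "protein %s: %d non-canonical letters mapped to X",
                pid, sum(a != b for a, b in zip(seq, cleaned)),
            )
        if len(cleaned) > max_length:
            raise ValueError(
                f"protein {pid!r} has length {len(cleaned)} > max_length "
                f"{max_length}; over-long sequences are rejected"
            )
        records.append(ProteinRecord(pid, cleaned))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ----------------------------------------------------------------------
# Region tables
# ----------------------------------------------------------------------

def read_regions(path, proteins: Sequence[ProteinRecord]) -> list[RegionAnnotation]:
    """Read a tab-separated region table (protein_id, label, start, end).

    Lines starting with '#' are comments. Every region is validated against
    the referenced protein's length.
    """
    lengths = {p.id: p.length for p in proteins}
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            pid, label, start_s, end_s = parts
            if pid not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown protein id {pid!r}")
            region = RegionAnnotation(pid, label, int(start_s), int(end_s))
            if region.end > lengths[pid]:
                raise ValueError(
                    f"{path}:{lineno}: region ({region.start}, {region.end}) "
                    f"exceeds length {lengths[pid]} of protein {pid!r}"
                )
            regions.append(region)
    return regions


def write_regions(regions: Iterable[RegionAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tlabel\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.protein_id}\t{r.label}\t{r.start}\t{r.end}\n")


def build_label_matrix(
    protein: ProteinRecord, regions: Iterable[RegionAnnotation]
) -> LabelMatrix:
    """Rasterize region annotations into an L x 7 binary matrix.

    Position p gets column c set iff some region with label c covers p.
    Overlapping regions of the same label are idempotent; region order is
    irrelevant.
    """
    mat = np.zeros((protein.length, N_LABELS), dtype=np.int8)
    col = {name: i for i, name in enumerate(LABELS)}
    for r in regions:
        if r.protein_id != protein.id:
            raise ValueError(
                f"region for {r.protein_id!r} passed with protein {protein.id!r}"
            )
        if r.end > protein.length:
            raise ValueError(
                f"region ({r.start}, {r.end}) exceeds protein length "
                f"{protein.length}"
            )
        mat[r.start - 1:r.end, col[r.label]] = 1  # 1-based incl -> 0-based half-open
    return LabelMatrix(protein.id, mat)


# ----------------------------------------------------------------------
# Embedding containers
# ----------------------------------------------------------------------

def write_embeddings(embeddings: Iterable[EmbeddingMatrix], path) -> None:
    """Write embeddings to an HDF5 container, one L x D dataset per protein."""
    with h5py.File(path, "w") as fh:
        for emb in embeddings:
            ds = fh.create_dataset(emb.protein_id, data=emb.vectors)
            ds.attrs["encoder_tag"] = emb.encoder_tag


def read_embeddings(path) -> dict[str, EmbeddingMatrix]:
    """Read an HDF5 embedding container into a dict keyed by protein id."""
    out: dict[str, EmbeddingMatrix] = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            tag = fh[pid].attrs.get("encoder_tag", "unknown")
            out[pid] = EmbeddingMatrix(pid, fh[pid][()], encoder_tag=str(tag))
    if not out:
        raise ValueError(f"embedding container {path} is empty")
    return out


def read_embedding_text(path, protein_id: str | None = None) -> EmbeddingMatrix:
    """Read a single per-protein plain-text embedding matrix (whitespace sep)."""
    path = Path(path)
    pid = protein_id or path.stem
    return EmbeddingMatrix(pid, np.loadtxt(path, ndmin=2), encoder_tag="text")


def one_hot_embeddings(protein: ProteinRecord) -> EmbeddingMatrix:
    """One-hot encoder over the 20 canonical amino acids plus X (D = 21)."""
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    idx = {a: i for i, a in enumerate(alphabet)}
    mat = np.zeros((protein.length, len(alphabet)))
    for i, aa in enumerate(protein.sequence):
        mat[i, idx[aa]] = 1.0
    return EmbeddingMatrix(protein.id, mat, encoder_tag="onehot21")


# ----------------------------------------------------------------------
# Prediction files
# ----------------------------------------------------------------------

def write_predictions(
    profile: PropensityProfile,
    thresholds: np.ndarray,
    sequence: str,
    path,
) -> None:
    """Write a CAID-style per-residue prediction file.

    Format: ``# protein_id``, ``# thresholds t1..t7``, then tab-separated
    ``pos residue 7xscore 7xbinary`` rows. Scores are recorded at 4 decimal
    places; the binary column is (score >= threshold) evaluated on the
    rounded score so the file is self-consistent on re-read.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.shape != (N_LABELS,):
        raise ValueError(f"thresholds must be a {N_LABELS}-vector")
    if profile.length != len(sequence):
        raise ValueError(
            f"profile length {profile.length} != sequence length {len(sequence)}"
        )
    # binarize against the written (4-decimal) values so the file is
    # self-consistent when re-read
    rounded = np.round(profile.scores, 4)
    thresholds = np.round(thresholds, 4)
    binary = (rounded >= thresholds[None, :]).astype(int)
    with open(path, "w") as fh:
        fh.write(f"# {profile.protein_id}\n")
        fh.write("# thresholds " + " ".join(f"{t:.4f}" for t in thresholds) + "\n")
        for p in range(profile.length):
            cells = [str(p + 1), sequence[p]]
            cells += [f"{s:.4f}" for s in rounded[p]]
            cells += [str(b) for b in binary[p]]
            fh.write("\t".join(cells) + "\n")


def read_predictions(path) -> tuple[PropensityProfile, np.ndarray, str]:
    """Read a prediction file back; returns (profile, thresholds, sequence)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# "):
            raise ValueError(f"{path}: missing '# protein_id' header")
        pid = header[2:].strip()
        thr_line = fh.readline().strip()
        if not thr_line.startswith("# thresholds"):
            raise ValueError(f"{path}: missing '# thresholds' header")
        thresholds = np.array([float(x) for x in thr_line.split()[2:]])
        scores, residues = [], []
        expect = 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pos = int(parts[0])
            if pos != expect:
                raise ValueError(f"{path}: positions not consecutive at {pos}")
            expect += 1
            residues.append(parts[1])
            row = [float(x) for x in parts[2:2 + N_LABELS]]
            binary = [int(x) for x in parts[2 + N_LABELS:2 + 2 * N_LABELS]]
            implied = [int(s >= t) for s, t in zip(row, thresholds)]
            if binary != implied:
                raise ValueError(
                    f"{path}: binary column inconsistent with thresholds at "
                    f"position {pos}"
                )
            scores.append(row)
    return (
        PropensityProfile(pid, np.array(scores)),
        thresholds,
        "".join(residues),
    )
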