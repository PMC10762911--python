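import numpy as np
import pytest

from disograph.io import (
    EmbeddingMatrix,
    LabelMatrix,
    ProteinRecord,
    RegionAnnotation,
    build_label_matrix,
)
from disograph.model import ModelConfig, init_params
from disograph.synth import SimConfig, simulate_dataset


@pytest.fixture
def tiny_model():
    """A small model with random parameters and a mildly coupled adjacency."""
    config = ModelConfig(embed_dim=6, bigru_hidden=4, attn_gru_hidden=5,
                         node_feature_dim=3, seed=11)
    ig = np.full((6, 6), 0.2)
    params = init_params(config, ig=ig)
    return config, params


@pytest.fixture
def tiny_embedding():
    rng = np.random.default_rng(3)
    return EmbeddingMatrix("P1", rng.standard_normal((9, 6)))


@pytest.fixture
def small_dataset():
    """A 6-protein synthetic dataset (proteins, regions, labels, embeddings)."""
    config = SimConfig(seed=5, n_proteins=6, embed_dim=16,
                       length_range=(20, 40))
    return simulate_dataset(config)


def label_matrix_from_columns(columns: dict[int, list[int]], L: int,
                              pid: str = "P") -> LabelMatrix:
    """Build an L x 7 label matrix with the given columns set."""
    mat = np.zeros((L, 7), dtype=int)
    for col, values in columns.items():
        mat[:, col] = values
    return LabelMatrix(pid, mat)
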