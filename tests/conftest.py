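import numpy as np
import pytest

from sclstm.io import ExpressionMatrix
from sclstm.siamese import SiameseConfig
from sclstm.synthetic import SyntheticSpec, simulate_counts


def small_expression(n=3, m=4, seed=0):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        values=rng.integers(0, 20, size=(n, m)).astype(float),
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
    )


def separable_spec(seed, k=4, n_cells=200, n_genes=2000,
                   proportions=(0.5, 0.25, 0.2, 0.05)):
    """Well-separated fixture: kernel-space silhouette of truth >= 0.5."""
    return SyntheticSpec(
        n_cells=n_cells, n_genes=n_genes, k=k, proportions=proportions,
        n_marker_genes_per_cluster=200, log_fold_change=2.5, seed=seed,
    )


def fast_siamese_config(seed=0, **overrides):
    """Training settings sized for test-suite budgets (seconds per fit)."""
    kw = dict(
        hidden_units=32, embed_mode="chunked", chunk_width=16, dense_units=32,
        epochs=60, batch_size=64, learning_rate=1e-2, pairs_per_cell=10,
        positive_fraction=0.5, seed=seed,
    )
    kw.update(overrides)
    return SiameseConfig(**kw)


def block_similarity(sizes, within=1.0, between=0.0):
    """Perfect block-structured similarity matrix and its block labels."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    M = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(M, 1.0)
    return M, labels


@pytest.fixture
def expr3x4():
    return small_expression(3, 4, seed=0)


@pytest.fixture(scope="session")
def separable_data():
    """One separable 4-cluster data set with a 10:1 minority class."""
    X, y = simulate_counts(separable_spec(seed=0))
    return X, y
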