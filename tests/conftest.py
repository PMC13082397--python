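import numpy as np
import pytest

from duast import ModelConfig, STDataset, build_knn_adjacency


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small preprocessed-scale dataset for fast training tests."""
    from duast import generate_st, preprocess_dataset

    ds, truth = generate_st(n_spots=100, n_genes=30, n_domains=2, n_svg=4,
                            seed=7)
    prep, kept = preprocess_dataset(ds)
    return prep, truth, kept


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    prep, _, _ = tiny_dataset
    return build_knn_adjacency(prep.coords, 4)


@pytest.fixture()
def fast_config():
    return ModelConfig(epochs=30, d3=16, d4=8, nsb_hidden=16,
                       disc_hidden=8, dec_hidden=16, seed=11)
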