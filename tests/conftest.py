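import pytest

import microgat.model
from microgat.network import build_network, induce_all
from microgat.synthetic_data import SimulationConfig, generate_dataset, make_toy_fixture


@pytest.fixture(autouse=True)
def _softmax_invariant_hook():
    """Assert softmax normalization on every forward pass of the suite."""
    microgat.model.CHECK_INVARIANTS = True
    yield
    microgat.model.CHECK_INVARIANTS = False


@pytest.fixture(scope="session")
def toy():
    table, embeddings, labels = make_toy_fixture()
    return table, embeddings, labels


@pytest.fixture(scope="session")
def small_dataset():
    """Small but realistic synthetic dataset for unit tests (not the study)."""
    cfg = SimulationConfig(
        seed=5, n_samples=60, n_genera=20, n_blocks=2, block_size=5,
        n_discriminative=4, embedding_dim=8,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    table, embeddings, labels, truth = small_dataset
    net = build_network(table, seed=3)
    return net, induce_all(net, table, embeddings)
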