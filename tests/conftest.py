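import numpy as np
import pytest

import assaybind as ab


@pytest.fixture(scope="session")
def small_collection():
    """A small deterministic synthetic collection shared across tests."""
    cfg = ab.SyntheticConfig(n_assays=6, seed=7)
    rng = np.random.default_rng(7)
    records, complexes, truth = ab.make_assay_collection(cfg, rng)
    return cfg, records, complexes, truth


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A narrow model for fast functional tests."""
    return ab.ModelConfig(
        encoder=ab.EncoderConfig(
            gnn=ab.GNNConfig(variant="GIN", n_layers=2, hidden_dim=8, dropout=0.0),
            interaction_dim=8,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
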