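import pytest

from embeddti import generate_synthetic_dataset
from embeddti.neural_model import ModelConfig, init_model_params, train_model


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig.small()


@pytest.fixture(scope="session")
def small_params(small_config):
    return init_model_params(small_config, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Ten noise-free synthetic records, enough for memorization checks."""
    return generate_synthetic_dataset(
        n_drugs=8, n_proteins=5, n_records=10, noise_sd=0.0, seed=3
    )


@pytest.fixture(scope="session")
def memorized_state(tiny_dataset):
    """A model trained to convergence on the ten-record set; shared across
    the prediction, screening and CLI tests."""
    config = ModelConfig.small(epochs=300, batch_size=10, learning_rate=0.005)
    return train_model(tiny_dataset, config, seed=4)
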