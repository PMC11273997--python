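import numpy as np
import pytest

from latentlink import simulate, vae


@pytest.fixture(scope="session")
def linear_spec():
    return simulate.make_spec()


@pytest.fixture(scope="session")
def linear_dataset(linear_spec):
    """Default one-factor all-linear sample at the study size."""
    return simulate.simulate_dataset(linear_spec, 1000, seed=11)


@pytest.fixture(scope="session")
def one_sigmoid_dataset():
    spec = simulate.make_spec(n_sigmoid_per_factor=1)
    return simulate.simulate_dataset(spec, 1000, seed=11)


@pytest.fixture(scope="session")
def four_sigmoid_dataset():
    spec = simulate.make_spec(n_sigmoid_per_factor=4)
    return simulate.simulate_dataset(spec, 1000, seed=11)


@pytest.fixture(scope="session")
def quick_vae_config():
    """Reduced epochs/folds for unit tests that only need a sane model."""
    return vae.VAEConfig(epochs=30, k_folds=3, seed=5)


@pytest.fixture(scope="session")
def trained_linear_vae(linear_dataset, quick_vae_config):
    return vae.train(linear_dataset.responses, quick_vae_config)


@pytest.fixture(scope="session")
def trained_linear_vae_full(linear_dataset):
    """Full study configuration (100 epochs, 10 folds) on the linear sample."""
    return vae.train(linear_dataset.responses, vae.VAEConfig(seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
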