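import numpy as np
import pytest

from neuroscca import generate_coupled_dataset, standardize_columns


@pytest.fixture(scope="session")
def planted_small():
    """A small, clearly recoverable planted dataset shared across tests."""
    X, Y, truth = generate_coupled_dataset(
        n=150, p=30, q=12, k_x=5, k_y=4, latent_strength=4.0, noise_sd=1.0, seed=11
    )
    return X, Y, truth


@pytest.fixture()
def standardized_planted(planted_small):
    X, Y, truth = planted_small
    Xs, _ = standardize_columns(X)
    Ys, _ = standardize_columns(Y)
    return Xs, Ys, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
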