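import numpy as np
import pytest

import ianam as ia


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_design():
    """A very small simulation design used across tests."""
    return ia.SimDesign(n=60, r=6, p=4, q=2, n_main=3, n_inter=3, seed=42)


@pytest.fixture(scope="session")
def tiny_data(tiny_design):
    train, test, truth = ia.make_dataset(tiny_design)
    return train, test, truth


@pytest.fixture
def random_ge_model(rng):
    return ia.GEModel(q=2, r=3, layer_sizes=(1, 4, 1), rng=rng)


@pytest.fixture
def random_imaging_model(rng):
    return ia.ImagingModel(q=2, p=3, layer_sizes=(1, 4, 1), rng=rng)


def randomize_nets(model, rng):
    """Give every layer (including the zero-initialized final one) random
    weights and biases, so nonlinearities are actually exercised."""
    for l, w in enumerate(model.nets.weights):
        w[:] = rng.standard_normal(w.shape) * 0.5
        model.nets.biases[l][:] = rng.standard_normal(
            model.nets.biases[l].shape
        ) * 0.1
    return model
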