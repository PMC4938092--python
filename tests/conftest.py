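import numpy as np
import pytest

from glmpp import (
    EventDataset,
    Kernel,
    NetworkModel,
    Nonlinearity,
    make_cosine_basis,
)


@pytest.fixture(scope="session")
def small_basis():
    """Coarse basis keeping small-instance likelihoods cheap."""
    return make_cosine_basis(n_basis=4, support=0.5, bin_width=0.01)


@pytest.fixture(scope="session")
def default_basis():
    return make_cosine_basis()


def random_dataset(rng, n_channels=3, duration=60.0, rate=0.5):
    channels = [f"c{k}" for k in range(n_channels)]
    events = {}
    for ch in channels:
        n = rng.poisson(rate * duration)
        events[ch] = np.sort(rng.uniform(0, duration, size=n).round(6))
    return EventDataset(channels, events, duration)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def excitation_pair_model(default_basis):
    """2-channel additive ground truth: one excitatory kernel u->v peaking
    at 0.25 s, all other kernels exactly zero."""
    from glmpp.simulate import _bump

    lags = default_basis.lag_grid
    curve = _bump(lags, 0.8, 0.25, 0.7)
    w = Kernel.from_curve(default_basis, lags, curve).weights
    W = np.zeros((2, 2, default_basis.n_basis))
    W[0, 1] = w
    nl = Nonlinearity("softplus", 0.1)
    b = np.array([nl.inverse(0.2), nl.inverse(0.2)])
    return NetworkModel(["u", "v"], b, W, default_basis, nl, "additive")
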