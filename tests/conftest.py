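import numpy as np
import pytest

import dixonsep as dx


@pytest.fixture(scope="session")
def params():
    return dx.default_params()


@pytest.fixture(scope="session")
def smooth_truth():
    return dx.generate_phantom(dx.smooth_spec(), seed=42)


@pytest.fixture(scope="session")
def noiseless_img(smooth_truth, params):
    return dx.simulate_acquisition(smooth_truth, params, noise_sigma=0.0)


def random_graph(seed: int, shape=(4, 4), radius=4.0):
    """Random penalty graph from uniform phasor candidate maps."""
    rng = np.random.default_rng(seed)
    s1 = rng.uniform(0.2, 1.0, shape)
    p1 = np.exp(1j * rng.uniform(-np.pi, np.pi, shape))
    p2 = np.exp(1j * rng.uniform(-np.pi, np.pi, shape))
    return dx.build_penalty_graph(s1, p1, p2, dx.NeighborSpec.disk(radius))
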