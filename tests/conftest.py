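import numpy as np
import pytest

import metacoex as mx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_species():
    """The worked S=2 example: masses (1, 16), default a0 = 2^(-1/2)."""
    return mx.build_interaction_matrix(np.array([1.0, 16.0]))


@pytest.fixture
def random_community(rng):
    """A generic metabolically generated community of moderate size."""
    cfg = mx.EnsembleConfig(S=12, n_communities=1, seed=7)
    masses = mx.sample_masses(cfg, rng)
    return mx.build_interaction_matrix(masses)
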