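import numpy as np
import pytest

import plastevol as pe


@pytest.fixture(scope="session")
def ref_dataset():
    """One study-shaped synthetic dataset shared across tests."""
    return pe.reference_dataset(seed=1)


@pytest.fixture()
def three_tip_tree():
    return pe.parse_trees("((A:1,B:1):0.5,C:1.5);")[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_tree(rng, n_tips):
    """A random tree with exponential branch lengths, via the simulator."""
    seed = int(rng.integers(2**31 - 1))
    return pe.simulate_tree(n_tips, birth=1.0, death=0.0, seed=seed)
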