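import numpy as np
import pytest

from nodulephylo import Grade, SimulationConfig, simulate_patient
from nodulephylo.matrix import CharacterMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160709)


@pytest.fixture
def quartet_matrix():
    """Clean split signal: A,B share 5 derived states, C,D share 5 others."""
    states = np.zeros((4, 10), dtype=int)
    states[0, :5] = states[1, :5] = 1
    states[2, 5:] = states[3, 5:] = 1
    return CharacterMatrix(list("ABCD"), [f"c{j}" for j in range(10)], states)


@pytest.fixture
def linear_patient():
    """One linear-model patient with fixed trunk/private counts and two
    tumor nodules (the 50-trunk/10-private worked configuration)."""
    config = SimulationConfig(
        model="linear",
        samples_per_patient=(Grade.CIRRHOSIS, Grade.LGDN, Grade.HCC),
        n_trunk_snv=50,
        n_private_snv=10,
        poisson_counts=False,
        subclonal_private=False,
        seed=11,
    )
    return config, simulate_patient(config, 0)


def tree_to_leafstate(matrix):
    """Map package taxa order onto oracle leaf ids 0..n-1."""
    return {i: matrix.states[i].tolist() for i in range(matrix.n_taxa)}
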