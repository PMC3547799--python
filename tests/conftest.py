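import numpy as np
import pytest

from punishnet.networks import Network, generate_ba_network
from punishnet.oracles import complete_graph

# one fixed hypothesis profile so property tests are reproducible run to run
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ba_small():
    """A 100-node BA network shared by engine-level tests."""
    return generate_ba_network(100, 2, seed=42)


@pytest.fixture(scope="session")
def ba_500():
    return generate_ba_network(500, 2, seed=7)


@pytest.fixture
def triangle():
    return Network(n_nodes=3, edges=np.array([[0, 1], [1, 2], [0, 2]]))


@pytest.fixture
def path2():
    """Two nodes joined by a single edge."""
    return Network(n_nodes=2, edges=np.array([[0, 1]]))


@pytest.fixture
def k6():
    return complete_graph(6)
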