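import warnings

import numpy as np
import pytest

from ecoscape.dynamics import find_attractors
from ecoscape.fixture import load_tristable, tristable_parameters
from ecoscape.landscape import mixture_from_attractors, reduce_bipartite
from ecoscape.networks import BipartiteNetwork, ModelParameters

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tristable_net():
    return load_tristable()


@pytest.fixture(scope="session")
def tristable_params():
    return tristable_parameters()


@pytest.fixture(scope="session")
def tristable_attractors(tristable_net, tristable_params):
    aset = find_attractors(tristable_net, tristable_params, n_starts=80, seed=5)
    assert aset.scenario == "HIL"
    return aset


@pytest.fixture(scope="session")
def tristable_projection(tristable_net, tristable_params, tristable_attractors):
    mix = mixture_from_attractors(
        tristable_attractors, tristable_net, tristable_params, d=0.01
    )
    return reduce_bipartite(mix, tristable_net)


@pytest.fixture(scope="session")
def toy_net():
    """One plant, one pollinator, fully connected."""
    return BipartiteNetwork(np.ones((1, 1)))


def toy_params(kappa):
    """Bistable (high/low) for kappa in about [0.9, 1.3]."""
    return ModelParameters(kappa=kappa, gamma0=2.0)


@pytest.fixture(scope="session")
def toy_bistable(toy_net):
    params = toy_params(1.15)
    aset = find_attractors(toy_net, params, n_starts=30, seed=0)
    assert aset.scenario == "HL"
    return params, aset
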