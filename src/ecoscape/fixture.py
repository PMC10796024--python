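"""Packaged tristable reference network.

A 17-plant x 13-pollinator sub-network obtained by removing 80% of the
pollinators of a synthetic 17 x 61 network (connectance 0.13, heterogeneous
degrees), selected by a seeded search for tristability.  At the default
parameters with ``kappa = 1.09`` it exhibits three stable states: high
(9/13 pollinators alive), intermediate (only the degree-9 generalist
pollinator alive) and low (all pollinators extinct).  The tristable window
is approximately ``kappa`` in [1.06, 1.11]; the high state folds near 1.115
and the intermediate state persists to about 1.145, so a slow increase of
``kappa`` produces a two-stage collapse with hysteresis.

The network ships as a CSV and is also exactly regenerable from the
documented seeds via :func:`regenerate_tristable`.
"""

from __future__ import annotations

from importlib import resources

from .networks import (
    BipartiteNetwork,
    ModelParameters,
    generate_random_network,
    read_weboflife_matrix,
    remove_pollinators,
)

#: seeds of the generating search (base network / pollinator removal)
BASE_SEED = 10147
REMOVAL_SEED = 11147
BASE_SHAPE = (17, 61)
BASE_CONNECTANCE = 0.13
BASE_HETEROGENEITY = 2.0
REMOVAL_FRACTION = 0.8

#: kappa at which the fixture is tristable (middle of the HIL window)
TRISTABLE_KAPPA = 1.09


def tristable_parameters() -> ModelParameters:
    """Default model parameters placing the fixture in its tristable regime."""
    return ModelParameters(kappa=TRISTABLE_KAPPA)


def regenerate_tristable() -> BipartiteNetwork:
    """Re-derive the fixture network from the documented seeds."""
    base = generate_random_network(
        *BASE_SHAPE,
        connectance=BASE_CONNECTANCE,
        heterogeneity=BASE_HETEROGENEITY,
        seed=BASE_SEED,
    )
    return remove_pollinators(base, REMOVAL_FRACTION, seed=REMOVAL_SEED)


def load_tristable() -> BipartiteNetwork:
    """Load the packaged 17 x 13 tristable network."""
    ref = resources.files("ecoscape").joinpath("data/tristable_17x13.csv")
    with resources.as_file(ref) as path:
        return read_weboflife_matrix(path)
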