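import dataclasses

import numpy as np
import pytest

from hipposim.model_core import (
    MechanicsParams,
    Population,
    ReactionParams,
    SimConfig,
    default_config,
    make_rng,
)


@pytest.fixture
def reaction_params() -> ReactionParams:
    return ReactionParams()


@pytest.fixture
def mech() -> MechanicsParams:
    return MechanicsParams()


@pytest.fixture
def normal_config() -> SimConfig:
    return default_config("normal")


@pytest.fixture
def cancer_config() -> SimConfig:
    return default_config("cancer")


@pytest.fixture
def rng() -> np.random.Generator:
    return make_rng(12345)


def make_population(positions, sigma=None, zeta=None, velocities=None,
                    X=None) -> Population:
    """Small helper building a population from raw positions."""
    mechp = MechanicsParams()
    zeta = zeta if zeta is not None else mechp.zeta
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    pop = Population(zeta=zeta)
    pop.add_cells(
        r=positions,
        v=np.zeros((n, 3)) if velocities is None else np.asarray(velocities, float),
        sigma=np.full(n, mechp.sigma0 if sigma is None else sigma),
        age=0.0,
        color=1,
        X=np.tile([0.05, 0.2, 0.0], (n, 1)) if X is None else np.asarray(X, float),
        rho=0.0,
    )
    return pop


@pytest.fixture
def short_config(normal_config) -> SimConfig:
    """Normal preset shrunk to a few hundred steps for loop-level tests."""
    return dataclasses.replace(normal_config, L=200, snapshot_every=50)
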