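import math

import numpy as np
import pytest

from polisoc import ModelParams, SocietyState, make_params


@pytest.fixture
def micro_params() -> ModelParams:
    """Two groups of three: the smallest society with nontrivial games."""
    return make_params(dict(G=2, n=3, B1=30.0, X0=5.0, B2=90.0, Z0=50.0,
                            c=1.0, pi0=1.0, alpha=1.0, epsilon=0.3,
                            mu1=0.25, mu2=0.25, lam=math.inf))


@pytest.fixture
def standard_params() -> ModelParams:
    """Eight equal groups of ten with per-capita benefits b1=20, b2=10."""
    return make_params(dict(G=8, n=10, B1=200.0, X0=5.0, B2=800.0, Z0=50.0,
                            c=1.0, pi0=1.0, alpha=1.0, epsilon=0.2,
                            mu1=0.25, mu2=0.25, lam=math.inf))


def random_state(params: ModelParams, rng: np.random.Generator
                 ) -> SocietyState:
    """A valid random state: Dirichlet powers, coin-flip strategies."""
    f = rng.dirichlet(np.ones(params.G))
    x = (rng.random(params.total_n) < 0.5).astype(np.int8)
    theta = (rng.random(params.G) < 0.5).astype(np.int8)
    state = SocietyState(x=x, theta=theta, f=f)
    X = state.group_efforts(params)
    state.theta[X == 0] = 0
    return state
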