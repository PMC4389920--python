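import numpy as np
import pytest

import plaqstab as p


@pytest.fixture(scope="session")
def grid24():
    return p.make_grid(1.0, 2.0, 24, 24, 1.0)


@pytest.fixture(scope="session")
def grid_small():
    return p.make_grid(1.0, 2.0, 8, 8, 1.0)


@pytest.fixture(scope="session")
def logistic_model():
    """Stable reference model: equilibrium at L_e = ln 3."""
    return p.ModelParameters(
        D_L=1.0, D_M=1.0, mu=0.1, k_L=1.0, k_M=1.0, k_N=1.0, L0=1.5,
        response=p.ResponseFunction.logistic(amplitude=2.0),
    )


@pytest.fixture(scope="session")
def logistic_eq_lc(logistic_model):
    eq = p.compute_equilibrium(logistic_model)
    lc = p.linearize(logistic_model, eq)
    return eq, lc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
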