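import numpy as np
import pytest

from quadstack.synth import SyntheticSAXSSpec, simulate_basis


@pytest.fixture(scope="session")
def saxs_basis():
    """Simulated (spec, I0, Iinf) basis shared across the suite.

    One T* = 0 and one T* = inf ensemble at the reduced desk-scale study
    conditions (300 dimers, 10 snapshots, 50 points per cylinder).
    """
    spec = SyntheticSAXSSpec(n_dimers=300, n_snapshots=10,
                             points_per_cylinder=50, rng_seed=3)
    i0, iinf = simulate_basis(spec)
    return spec, i0, iinf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
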