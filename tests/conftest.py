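"""Shared fixtures: one library/basis/regressor pair reused across the suite."""

import numpy as np
import pytest

from pipedmri import factorization as fz
from pipedmri import phantom as ph
from pipedmri import training as tr

# scaled-down library defaults used throughout the tests (full-size defaults
# are 50000 x 1000; 5000 x 128 keeps every tolerance intact within budget)
LIB_N_XI = 5000
LIB_N_B = 128
LIB_SEED = 0


@pytest.fixture(scope="session")
def library():
    return fz.build_library(n_xi=LIB_N_XI, n_b=LIB_N_B, seed=LIB_SEED)


@pytest.fixture(scope="session")
def basis(library):
    """Estimation-grade basis: 4 components for l=0, 3 for l=2."""
    return fz.svd_factorize(library, n_components={0: 4, 2: 3})


@pytest.fixture(scope="session")
def basis55(library):
    """Factorization-accuracy basis with 5 components per degree."""
    return fz.svd_factorize(library, n_components={0: 5, 2: 5})


@pytest.fixture(scope="session")
def ref_protocol():
    """Reference shelled protocol: 5 b=0 + (1, 25), (2, 60), (8, 50)."""
    return ph.make_shelled_protocol(n_b0=5, seed=1)


@pytest.fixture(scope="session")
def reg_snr50(basis, ref_protocol):
    noise = {"snr": 50.0, "b": ref_protocol.b, "g": ref_protocol.g}
    ts = tr.make_training_set(basis, 30_000, noise_config=noise, seed=3)
    return tr.fit_polynomial(ts, degree=3)


@pytest.fixture(scope="session")
def reg_noiseless(basis):
    ts = tr.make_training_set(basis, 30_000, noise_config=None, seed=3)
    return tr.fit_polynomial(ts, degree=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_unit_vectors(n, seed=0):
    r = np.random.default_rng(seed)
    v = r.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
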