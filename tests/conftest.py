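import numpy as np
import pytest

from codock.fixtures import FixtureConfig, make_library, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic receptor/ligand/topology triple shared across tests."""
    return make_toy_complex(FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def toy_library(toy_complex):
    return make_library(10, toy_complex, FixtureConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
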