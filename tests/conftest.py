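import numpy as np
import pytest

from ionsans.synthetic import ToyChannelSpec, build_toy_channel


@pytest.fixture(scope="session")
def toy():
    """Default toy pentamer and its ground-truth report."""
    return build_toy_channel(ToyChannelSpec())


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
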