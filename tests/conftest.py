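import numpy as np
import pytest

from cyclodesc.lipo_scale import load_default_scale


@pytest.fixture(scope="session")
def scale():
    return load_default_scale()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
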