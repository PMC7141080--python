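import numpy as np
import pytest

from gazecal.calibration import ResidualSet
from gazecal.correction import CorrectionField
from gazecal.synthetic import generate_session


@pytest.fixture(scope="session")
def noiseless_session():
    """2 s head-rotation sweep at 114 Hz with zero pupil noise (228 rows)."""
    return generate_session("head-rotation", duration_s=2.0, noise_sd_px=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_session():
    """5 s head-rotation sweep with 2 px pupil noise."""
    return generate_session("head-rotation", duration_s=5.0, noise_sd_px=2.0, seed=3)


@pytest.fixture
def tri_field():
    """Three-node correction field used by the hand-checkable IDW examples."""
    nodes = ResidualSet(
        node_xy=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
        node_t=np.array([0.0, 100.0, 200.0]),
        vectors=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )
    return CorrectionField(nodes, r=2.0, window_ms=200.0)


def brute_force_idw(node_xy, vectors, p, r):
    """Direct summation of the Shepard interpolation formula (test oracle)."""
    num = np.zeros(2)
    den = 0.0
    for (x, y), v in zip(node_xy, vectors):
        d = ((x - p[0]) ** 2 + (y - p[1]) ** 2) ** 0.5
        if d == 0.0:
            raise ZeroDivisionError
        num = num + np.asarray(v) / d**r
        den += 1.0 / d**r
    return num / den
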