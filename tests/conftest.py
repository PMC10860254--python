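import numpy as np
import pytest

from cephmetrics import tables
from cephmetrics.muenster22 import calibrate_spacing


@pytest.fixture(scope="session")
def ref_a():
    """Packaged expert reference for image A."""
    return tables.reference_set("A")


@pytest.fixture(scope="session")
def ref_a_landmarks(ref_a):
    return ref_a.landmark_set


@pytest.fixture(scope="session")
def spacing_a(ref_a_landmarks):
    """Pixel spacing calibrated from the printed convexity of point A."""
    return calibrate_spacing(ref_a_landmarks, "convexity_point_a", 3.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20240212)
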