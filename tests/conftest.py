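import numpy as np
import pytest

from mpod.models import GRAND_MEAN_M3G, M3GParams, ModelCurve, ModelKind
from mpod.profiles import default_radii


@pytest.fixture(scope="session")
def grand_mean_curve() -> ModelCurve:
    """Three-Gaussian model at the published cohort grand-mean parameters."""
    return ModelCurve(ModelKind.M3G, GRAND_MEAN_M3G)


@pytest.fixture(scope="session")
def unit_gaussian() -> ModelCurve:
    """Single centred unit Gaussian (N=1, q=1, g=0), closed forms known."""
    return ModelCurve(ModelKind.M3G, M3GParams(
        N1=1.0, N2=0.0, N3=0.0, q1=1.0, q2=1.0, q3=1.0, g1=0.0, g2=0.0, g3=0.0))


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return default_radii()
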