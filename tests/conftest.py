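import numpy as np
import pytest

from hydromix.mixing_power import PowerCorrelation, ReactorGeometry
from hydromix.rheology import calibrate_rheology
from hydromix.synthetic_data import (
    SlurryComposition,
    calibrate_conversion_model,
    dilute_slurry,
)


@pytest.fixture(scope="session")
def printed_correlation():
    return PowerCorrelation(k1=346.7, k2=1.27)


@pytest.fixture(scope="session")
def geometry():
    return ReactorGeometry()


@pytest.fixture(scope="session")
def illustration_rheology():
    """Anchor-pinned model with the round illustration exponents b=5, n=0.5."""
    return calibrate_rheology(2.0, 12.0, 50.0, b=5.0, n_pl=0.5)


@pytest.fixture(scope="session")
def base_composition():
    return SlurryComposition()


@pytest.fixture(scope="session")
def diluted_composition(base_composition):
    return dilute_slurry(base_composition, target_wis=10.0).composition


@pytest.fixture(scope="session")
def conversion_params():
    return calibrate_conversion_model()


@pytest.fixture(scope="session")
def time_grid():
    return np.arange(0.0, 96.5, 0.5)
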