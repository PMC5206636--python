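import numpy as np
import pytest

from pulsedox import MediumParameters


@pytest.fixture
def cord_params_fig5_left():
    """Smallest in-vivo wall consumption rate, thin vessel."""
    return MediumParameters(D=2000.0, gamma0=0.0, gammaC=1.66e-4,
                            lambdaC=120.0, R=3.0)


@pytest.fixture
def cord_params_fig5_right():
    """Largest in-vivo wall consumption rate, thin vessel."""
    return MediumParameters(D=2000.0, gamma0=0.0, gammaC=5e-3,
                            lambdaC=120.0, R=3.0)


@pytest.fixture
def cord_params_mean():
    """Mean in-vivo wall consumption rate, thin vessel."""
    return MediumParameters(D=2000.0, gamma0=0.0, gammaC=2.16e-3,
                            lambdaC=120.0, R=3.0)


@pytest.fixture
def r_grid_400():
    return np.linspace(3.0, 403.0, 41)
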