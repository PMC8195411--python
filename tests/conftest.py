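import numpy as np
import pytest

from scobs import ObserverParams, OrientationGrid


@pytest.fixture(scope="session")
def grid():
    """Default quadrature grid used across tests."""
    return OrientationGrid(-90.0, 90.0, 0.2)


@pytest.fixture(scope="session")
def exp1_params():
    """Symmetric-design observer: sensory noise matching the stimulus widths."""
    return ObserverParams.symmetric(3.0, 18.0, 4.0, 24.0, 8.0, sigma_0=1.5)


@pytest.fixture(scope="session")
def exp2_params():
    """Asymmetric-design observer with the true-range prior widths."""
    return ObserverParams(
        sigma_s_low=6.0,
        sigma_s_high=18.0,
        sigma_m=4.0,
        alpha_cw=30.0,
        alpha_ccw=12.0,
        beta=8.0,
        p_cw=0.5,
        sigma_0=1.5,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
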