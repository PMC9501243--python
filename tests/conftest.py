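import numpy as np
import pytest

from eisgrowth import CircuitParams, FrequencyGrid


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    """Default 61-point log-spaced sweep, 10 Hz to 1 MHz."""
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def canonical_params() -> CircuitParams:
    """Canonical-scale parameter set used throughout the fitting tests."""
    return CircuitParams(a0=5.0, b0=-2.0e4, c0=-500.0, d0=2.0e-5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
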