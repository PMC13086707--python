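import numpy as np
import pytest

from mothpupil import (
    DEFAULT_CAMERA,
    IDENTITY_CAMERA,
    BumpParams,
    KineticTruth,
    NoiseModel,
    simulate_induced_series,
)


@pytest.fixture
def camera():
    """Measured NIR USB-microscope transfer function."""
    return DEFAULT_CAMERA


@pytest.fixture
def identity_camera():
    return IDENTITY_CAMERA


@pytest.fixture
def closing_truth():
    return KineticTruth(b=2.5, t50_s=300.0)


@pytest.fixture
def opening_truth():
    return KineticTruth(b=-2.5, t50_s=1800.0)


@pytest.fixture
def bump():
    return BumpParams(peak_height=0.3, peak_time_s=120.0, decay_tau_s=200.0)


@pytest.fixture
def noiseless_closing_series(closing_truth):
    """15-min UV-closing recording at 1 frame/s, identity camera, no noise."""
    return simulate_induced_series(closing_truth, duration_s=900.0, dt_s=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
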