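import numpy as np
import pytest

from colloidpulse import kinetics


@pytest.fixture(scope="session")
def default_params() -> kinetics.KineticParams:
    return kinetics.KineticParams()


@pytest.fixture(scope="session")
def default_pulse(default_params) -> kinetics.RnaTrajectory:
    """The default fuel-limited transient pulse on a half-minute grid."""
    t = np.arange(0.0, 300.5, 0.5)
    return kinetics.simulate(default_params, t, consume_fuel=True)
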