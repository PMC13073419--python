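import numpy as np
import pytest

from remact.counts import TriaxialRecording
from remact.synthetic import SimulationConfig, simulate_participant


@pytest.fixture(scope="session")
def short_night():
    """One 2 h synthetic participant used by several suites (read-only)."""
    return simulate_participant(SimulationConfig(seed=11), n_epochs=240)


@pytest.fixture()
def still_recording():
    """60 s of pure gravity at 50 Hz (magnitude exactly 1 g)."""
    n = 50 * 60
    return TriaxialRecording(
        sampling_rate=50.0, x=np.zeros(n), y=np.zeros(n), z=np.ones(n)
    )


def make_recording(x, y, z, rate=50.0, side="L"):
    return TriaxialRecording(sampling_rate=rate, x=x, y=y, z=z, side=side)
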