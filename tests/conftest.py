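import numpy as np
import pytest
from hypothesis import settings

import imubreath as ib

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pretest_traces():
    """Simulated trained-breather trials: 5 persons, 3 x 60 s each."""
    return ib.simulate_pretest_traces(seed=11)


@pytest.fixture(scope="session")
def reference_model(pretest_traces):
    return ib.fit_reference_model(pretest_traces)


@pytest.fixture(scope="session")
def matched_trace():
    """A 300 s recording whose tilt amplitude matches the pretest fixture mean."""
    cfg = ib.SimulationConfig(duration=300.0, breathing_freq=0.1,
                              tilt_amplitude=7.0, noise_sd=0.0, seed=5,
                              baseline_orientation=ib.default_mount_orientation())
    return ib.simulate_breathing_trace(cfg)
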