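import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tjpatch as tj

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def induced_scenario():
    """10 s claudin-2-induced recording plus its ground truth."""
    return tj.make_scenario("cldn2_induced", 11, duration=10.0)


@pytest.fixture(scope="session")
def long_single_channel_record():
    """500 s of one claudin-2 channel: simulate, render, idealize.

    Shared by the kinetics tests; long enough to sample ~150 visits to
    the long-lived closed state.
    """
    from tjpatch.protocol import hold
    from tjpatch.recording import RecordingConfig, render_current

    model = tj.claudin2_model()
    path = tj.simulate_state_path(model, 500.0, 42)
    cfg = RecordingConfig(duration=500.0, rng_seed=7)
    trace = render_current([path], hold(-100.0, 500.0), cfg)
    record = tj.detect_events(trace, 9.0, 0.2e-3)
    return model, path, record
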