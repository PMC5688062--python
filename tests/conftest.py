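import pytest

import meaflow as mf


@pytest.fixture(scope="session")
def layout():
    return mf.default_layout()


@pytest.fixture(scope="session")
def sim_recording(layout):
    """A shared 10-minute simulated recording with default parameters."""
    params = mf.SimulationParams(seed=123)
    spikes, truth = mf.simulate_recording(params, layout, 600.0)
    return params, spikes, truth


@pytest.fixture(scope="session")
def clean_recording(layout):
    """Background-free recording: every spike belongs to a burst."""
    params = mf.SimulationParams(seed=77, background_rate=0.0)
    spikes, truth = mf.simulate_recording(params, layout, 600.0)
    return params, spikes, truth
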