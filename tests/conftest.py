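import numpy as np
import pytest

from scgbeat.sim import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """A 60 s default-condition recording with its known beats."""
    return simulate_recording(SimConfig(duration_s=60.0, seed=42))


@pytest.fixture(scope="session")
def end_to_end_result():
    """Train the scaled network once per session and score it.

    Shared by the acceptance test and any test needing a trained model.
    """
    from scgbeat.experiments import run_end_to_end

    return run_end_to_end(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
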