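import numpy as np
import pytest

from shredsim import DemogParams, DriveParams, SimConfig, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline_drive():
    return DriveParams()


@pytest.fixture
def small_config():
    """A quick-running configuration for engine-level tests."""
    return SimConfig(
        demog=DemogParams(carrying_capacity=600),
        inoculum_size=12,
        years=10,
        replicates=5,
        seed=7,
    )


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    # Compile the mate-allocation kernel once so individual tests aren't
    # charged for it.
    cfg = SimConfig(demog=DemogParams(carrying_capacity=50), inoculum_size=2, years=1)
    run_simulation(cfg, seed=0)
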