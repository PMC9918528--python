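import numpy as np
import pytest

import suvrdyn as sd
from suvrdyn.timecourse import TimeGrid


@pytest.fixture(scope="session")
def grid():
    return sd.default_grid()


@pytest.fixture(scope="session")
def dense_grid():
    return TimeGrid(np.arange(0.0, 90.0001, 0.01))


@pytest.fixture(scope="session")
def iv_trajectory(dense_grid):
    """Canonical IV occupancy/dopamine trajectory."""
    return sd.simulate_occupancy_da(sd.MPKineticParams(), sd.MPPlasmaParams(),
                                    sd.DAParams(), dense_grid)


@pytest.fixture(scope="session")
def placebo_tacs(dense_grid):
    """Canonical noiseless placebo reference and target TACs (dense grid)."""
    ref = sd.simulate_reference_tac(sd.RacloInputParams(),
                                    sd.ReferenceKineticParams(), dense_grid)
    tgt = sd.simulate_target_tac(ref, sd.LSSRMParams(gamma=0.0), None,
                                 dense_grid)
    return ref, tgt


@pytest.fixture(scope="session")
def placebo_tacs_1min(grid, placebo_tacs):
    ref, tgt = placebo_tacs
    return (sd.TimeCourse(grid, ref.interp(grid.times), "reference"),
            sd.TimeCourse(grid, tgt.interp(grid.times), "target"))
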