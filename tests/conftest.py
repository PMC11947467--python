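import numpy as np
import pytest

from crowdcycle import (
    Grid,
    InitialCondition,
    ModelParameters,
    POSTERIOR_MODES,
)


@pytest.fixture(scope="session")
def modes() -> ModelParameters:
    """Calibrated reference parameter set for the MDCK expansion data."""
    return POSTERIOR_MODES


@pytest.fixture
def step_ic_1d():
    """Low-density step block (500/500 cells/mm^2 below 850 um) on a 1-D
    grid, the canonical traveling-wave initial condition."""

    def make(L: float = 8000.0, N: int = 400) -> tuple[Grid, InitialCondition]:
        grid = Grid("cartesian1d", L, N)
        block = grid.nodes < 850.0
        ic = InitialCondition(
            rho1=np.where(block, 500.0, 0.0), rho2=np.where(block, 500.0, 0.0)
        )
        return grid, ic

    return make
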