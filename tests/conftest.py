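import numpy as np
import pytest

from emipac import ComodulogramGrid
from emipac.simulate import BurstModelParams, gen_coupled_bursts


@pytest.fixture(scope="session")
def reduced_grid():
    """Desk-scale comodulogram grid used throughout the suite."""
    return ComodulogramGrid(f_p=np.arange(2.0, 10.5, 1.0),
                            f_a=np.arange(40.0, 125.0, 5.0),
                            delta_f_p=1.0)


@pytest.fixture(scope="session")
def coupled_signal():
    """Default coupled-bursts realisation shared across tests."""
    return gen_coupled_bursts(BurstModelParams(noise_level=0.05), seed=101)


@pytest.fixture(scope="session")
def coupled_emi_result(coupled_signal, reduced_grid):
    """One eMI analysis of the coupled-bursts signal, shared across tests."""
    from emipac import run_emi
    return run_emi(coupled_signal, reduced_grid, n_surr=60, seed=11)
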