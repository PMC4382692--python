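import numpy as np
import pytest

from aquadyn import synthetic as syn
from aquadyn.qens_model import SpectrumGrid, symmetric_energy_grid


@pytest.fixture(scope="session")
def small_grid():
    """Reduced instrument grid: 5 q values, 0.1 ueV channels, +-15.8 ueV."""
    return syn.default_qens_grid(n_q=5, channel=0.1)


@pytest.fixture(scope="session")
def small_resolution(small_grid):
    return syn.generate_resolution(small_grid)


@pytest.fixture(scope="session")
def small_truth(small_grid):
    return syn.default_qens_truth(n_q=small_grid.n_q)


@pytest.fixture(scope="session")
def noisy_dataset(small_grid, small_resolution, small_truth):
    return syn.generate_qens_dataset(small_truth, small_grid, small_resolution,
                                     syn.NoiseSpec(c=0.02, seed=11))


@pytest.fixture(scope="session")
def wide_grid():
    """Very wide energy window for quadrature checks of broad Lorentzians."""
    return SpectrumGrid(q_values=np.linspace(0.46, 1.66, 3),
                        E_values=symmetric_energy_grid(1000.0, 0.17))
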