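import numpy as np
import pytest

from eemquench.core import EEM, WavelengthGrid
from eemquench.synth import coarse_grid


@pytest.fixture
def toy_grid() -> WavelengthGrid:
    return WavelengthGrid([274.0, 276.0, 278.0, 280.0], [310.0, 312.0, 314.0])


@pytest.fixture
def toy_eem(toy_grid) -> EEM:
    rng = np.random.default_rng(42)
    return EEM(toy_grid, rng.uniform(0.0, 10.0, size=toy_grid.shape))


@pytest.fixture
def small_grid() -> WavelengthGrid:
    """Coarse instrument-range grid that keeps PARAFAC fits fast."""
    return coarse_grid()


@pytest.fixture
def tiny_grid() -> WavelengthGrid:
    """Very coarse grid for the slowest iterative tests."""
    return coarse_grid(ex_step=12.0, em_step=9.52)
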