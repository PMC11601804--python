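import numpy as np
import pytest

import twinpeak as tp


@pytest.fixture(scope="session")
def medium():
    return tp.Medium()


@pytest.fixture(scope="session")
def source():
    return tp.ARFSource()


@pytest.fixture(scope="session")
def default_grid():
    return tp.SamplingGrid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse, short grid for full-field / equivalence tests."""
    return tp.SamplingGrid(dx=0.5e-3, dt=0.2e-3, xmax=12e-3, tmax=8e-3,
                           dy=1.0e-3, ymax=6e-3, dz=2.0e-3, zmax=6e-3)


@pytest.fixture(scope="session")
def kv_params():
    return tp.KelvinVoigtParams(G0=2000.0, tau=0.5e-3)


@pytest.fixture(scope="session")
def kv_model(kv_params):
    return tp.RheologyModel.kelvin_voigt(kv_params.G0, kv_params.tau)


@pytest.fixture(scope="session")
def kv_field_2d(kv_params, medium, source, default_grid):
    """Observed x-t field of the default Kelvin-Voigt configuration (2D)."""
    return tp.simulate_time_kv(kv_params, medium, source, default_grid,
                               dims=2, observe=tp.Observation())


@pytest.fixture(scope="session")
def kv_field_3d(kv_model, medium, source, default_grid):
    """Observed x-t field from the 3D data-generation protocol."""
    return tp.generate_insilico(kv_model, medium, source, default_grid, dims=3)
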