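import numpy as np
import pytest

from mpi_deblur.forward_model import SimulationParams, build_psf


@pytest.fixture(scope="session")
def params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def psf(params):
    """Default PSF at the image pixel scale (0.8 mm/px, 21 px kernel)."""
    return build_psf(params, fov_mm=16.8, grid_px=21)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
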