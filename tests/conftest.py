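import numpy as np
import pytest

from menpi.config import RunConfig
from menpi.phantom import assign_conductivities, make_layered_phantom
from menpi.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64 mm^3 layered phantom with study conductivities."""
    return assign_conductivities(make_layered_phantom())


@pytest.fixture(scope="session")
def small_phantom():
    """A small layered phantom for fast imaging/demodulation tests."""
    return assign_conductivities(
        make_layered_phantom(shape=(32, 32, 32), voxel_size_mm=1.0, radii_mm=(8, 10, 12))
    )


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-configuration pipeline run, shared across tests."""
    return run_pipeline(RunConfig(seed=7), output_dir="")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
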