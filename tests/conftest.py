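import numpy as np
import pytest

from mpimet import ScannerConfig, TracerModel, build_operator


@pytest.fixture(scope="session")
def tracer():
    return TracerModel()


@pytest.fixture(scope="session")
def small_config():
    """A fast desk-scale 2D scanner: 16.5 mm FOV, 0.5 mm voxels, 2 angles."""
    return ScannerConfig(fov=(16.5, 16.5), grid=(33, 33), angles=(0.0, 90.0))


@pytest.fixture(scope="session")
def small_operator(tracer, small_config):
    return build_operator(tracer, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
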