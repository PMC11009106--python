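import numpy as np
import pytest

from landreg.detector import DetectorConfig, build_detector
from landreg.synthetic import SyntheticSpec, make_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    return DetectorConfig(n_landmarks=8, input_channels=3, input_size=64, scale="reduced")


@pytest.fixture(scope="session")
def tiny_detector(tiny_config):
    return build_detector(tiny_config, seed=0)


@pytest.fixture(scope="session")
def desk_spec():
    return SyntheticSpec(image_size=64)


@pytest.fixture(scope="session")
def tissue_sections(desk_spec):
    gen = np.random.default_rng(42)
    return [make_tissue(desk_spec, gen)[0] for _ in range(8)]
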