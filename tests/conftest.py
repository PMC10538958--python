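import numpy as np
import pytest

from ifomics.synthetic import StudyDesign, default_design


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return default_design()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
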