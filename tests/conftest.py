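import numpy as np
import pytest

from swirmc import OpticalPropertyTable


@pytest.fixture(scope="session")
def table() -> OpticalPropertyTable:
    return OpticalPropertyTable.default()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210712)
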