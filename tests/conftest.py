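import numpy as np
import pytest

from xbridge import ModelParameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The packaged default parameter set (shared, treated as read-only)."""
    return ModelParameters.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
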