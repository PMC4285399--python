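import numpy as np
import pytest

from painpath import generate_design


@pytest.fixture(scope="session")
def design_two():
    """Two-subject design, enough to see both counterbalancing arms."""
    return generate_design(2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
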