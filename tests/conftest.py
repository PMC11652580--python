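import numpy as np
import pytest

from asymcoal.io_cli import generate_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def oracle_fixtures():
    """Tiny exactly-enumerable models with brute-force transition tables."""
    return generate_fixtures()
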