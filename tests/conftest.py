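import numpy as np
import pytest

from hbbhaplo.haplotypes import default_table
from hbbhaplo.synthetic import default_template


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
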