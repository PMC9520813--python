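import numpy as np
import pytest

from caseonly import TwoByFourTable


@pytest.fixture
def table():
    """Reference 2x4 table: margins all 200, so S and E are exactly
    independent in the full sample while the interaction is strong."""
    return TwoByFourTable(a=10, B=190, c=20, D=180, e=30, F=170, g=120, H=80)


@pytest.fixture
def dependent_table():
    """Table whose full-sample margins encode an S-E association."""
    return TwoByFourTable(a=10, B=90, c=20, D=80, e=30, F=70, g=120, H=30)


@pytest.fixture
def uniform_table():
    return TwoByFourTable(*([10] * 8))


def random_tables(n, seed, low=5, high=200):
    """Valid random 2x4 tables with no zero cells."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        cells = rng.integers(low, high, size=8)
        yield TwoByFourTable(*[float(v) for v in cells])
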