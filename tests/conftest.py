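import numpy as np
import pandas as pd
import pytest

from minorsplice import clinical


@pytest.fixture(scope="session")
def table1():
    return clinical.load_table1()


@pytest.fixture(scope="session")
def table2():
    return clinical.load_table2()


@pytest.fixture(scope="session")
def combined(table1, table2):
    return table1 + table2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Tiny retained/spliced count pair used across intron-retention tests."""
    idx = ["i1", "i2", "i3"]
    cols = ["s1", "s2"]
    retained = pd.DataFrame([[0, 0], [30, 30], [3, 3]], index=idx, columns=cols)
    spliced = pd.DataFrame([[50, 50], [30, 30], [2, 2]], index=idx, columns=cols)
    return retained, spliced
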