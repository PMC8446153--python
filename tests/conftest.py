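import numpy as np
import pytest

import canardnmm as cn
from canardnmm import orbits


@pytest.fixture(scope="session")
def p_table1():
    return cn.table1()


@pytest.fixture(scope="session")
def folds(p_table1):
    return cn.fold_points(p_table1)


@pytest.fixture(scope="session")
def bursting_cycle():
    """Converged 4-spike bursting attractor (B=5, C3=80, C5=350)."""
    q = cn.table1().with_(B=5.0, C3=80.0, C5=350.0)
    return orbits.find_limit_cycle(q, orbits._LARGE_IC)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
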