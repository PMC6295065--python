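import numpy as np
import pandas as pd
import pytest

from l1mda import FixtureSpec, global_loocv, local_loocv, make_fixture


@pytest.fixture(scope="session")
def toy_4x2():
    """4 miRNAs x 2 diseases: two similar pairs (0.9) with weak cross links."""
    w_m = pd.DataFrame(
        np.array(
            [
                [1.0, 0.9, 0.1, 0.1],
                [0.9, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.9],
                [0.1, 0.1, 0.9, 1.0],
            ]
        ),
        index=list("abcd"),
        columns=list("abcd"),
    )
    a = pd.DataFrame(
        np.array([[1, 0], [0, 0], [0, 1], [0, 0]]),
        index=list("abcd"),
        columns=["x", "y"],
    )
    return w_m, a


@pytest.fixture(scope="session")
def planted():
    """The default planted-block study conditions (20x12, 3 blocks, seed 0)."""
    return make_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def planted_global_cv(planted):
    return global_loocv(planted.W_m, planted.W_d, planted.A)


@pytest.fixture(scope="session")
def planted_local_cv(planted):
    return local_loocv(planted.W_m, planted.W_d, planted.A)
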