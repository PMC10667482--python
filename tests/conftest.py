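import numpy as np
import pandas as pd
import pytest

import microconfig as mc


@pytest.fixture(scope="session")
def small_cohort():
    """One small mixed cohort (30 control, 30 CD, 20 HS) shared across tests."""
    return mc.generate_cohort(mc.small_spec(n_hs=20), seed=11)


@pytest.fixture(scope="session")
def small_null_cohort():
    return mc.generate_null_cohort(mc.small_spec(n_hs=20), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_table():
    """3 samples x 4 genera counts table with one never-present genus."""
    frame = pd.DataFrame(
        [[2, 2, 0, 0], [5, 0, 1, 0], [1, 3, 4, 0]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB", "gC", "gD"],
    )
    return mc.AbundanceTable(frame, mode="counts")
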