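import numpy as np
import pandas as pd
import pytest

from ftstab.tables import AbundanceTable
from ftstab.simulate import small_config, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def counts_table(rng):
    data = pd.DataFrame(
        rng.integers(0, 200, size=(5, 6)),
        index=[f"s{i}" for i in range(5)],
        columns=[f"f{j}" for j in range(6)],
    )
    return AbundanceTable(data=data, domain="bacteria", scale="counts")


@pytest.fixture()
def relative_table(rng):
    raw = rng.random((6, 5)) + 0.05
    data = pd.DataFrame(
        raw / raw.sum(axis=1, keepdims=True),
        index=[f"s{i}" for i in range(6)],
        columns=[f"f{j}" for j in range(5)],
    )
    return AbundanceTable(data=data, domain="function", scale="relative")


@pytest.fixture(scope="session")
def small_dataset():
    """One small coupled synthetic dataset shared across tests."""
    return generate_dataset(small_config(seed=11))
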