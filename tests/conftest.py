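import numpy as np
import pandas as pd
import pytest

from tknet.containers import AbundanceTable
from tknet.synthetic import StudyConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def counts_table():
    """Small deterministic count table with metadata for two experiments."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.integers(0, 500, size=(12, 8)),
        index=[f"OTU{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    data.iloc[0, :] += 2000  # a dominant feature
    metadata = pd.DataFrame(
        {
            "experiment": ["exp1"] * 4 + ["exp2"] * 4,
            "group": ["ND", "ND", "WD", "WD"] * 2,
            "compartment": ["ileum8"] * 8,
            "timepoint": ["8wk"] * 8,
        },
        index=data.columns,
    )
    return AbundanceTable(data=data, metadata=metadata)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by network-level tests."""
    return generate_study(StudyConfig(seed=11, n_otus=30, n_per_group=16))
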