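import numpy as np
import pandas as pd
import pytest

from mmuphin.data_model import FeatureTable, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """8 samples x 5 features, positive counts with some zeros."""
    values = rng.integers(0, 50, size=(8, 5)).astype(float)
    values[0, 0] = 0.0
    values[3, 2] = 0.0
    values[:, 4] += 1.0  # keep one feature always present
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(8)],
                      columns=[f"f{j}" for j in range(5)])
    return FeatureTable(df)


@pytest.fixture
def two_batch_meta():
    idx = [f"s{i}" for i in range(8)]
    return SampleMetadata(
        pd.DataFrame({"batch": ["a"] * 4 + ["b"] * 4,
                      "group": ["x", "y"] * 4}, index=idx)
    )
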