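import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def leaf_table():
    """Three shoots of one species with hand-checkable aggregates."""
    return pd.DataFrame(
        {
            "shoot": ["s1", "s1", "s1", "s2", "s3", "s3"],
            "species": ["sp"] * 6,
            "length": [5.0, 4.0, 6.0, 10.0, 7.0, 8.0],
            "width": [1.0, 2.0, 3.0, 2.0, 1.5, 2.5],
            "area": [3.6, 5.8, 13.0, 14.0, 7.5, 14.2],
        }
    )
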