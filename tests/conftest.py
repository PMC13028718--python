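import numpy as np
import pandas as pd
import pytest

from biocrust import AbundanceTable, SampleMetadata


@pytest.fixture
def tiny_table():
    return AbundanceTable(["s1", "s2"], ["a", "b", "c"], np.array([[5, 0, 1], [2, 2, 2]]))


@pytest.fixture
def six_sample_meta():
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(1, 7)],
                "group": ["A", "A", "A", "B", "B", "B"],
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
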