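import numpy as np
import pandas as pd
import pytest

from microbialite.ecology import CountTable


@pytest.fixture
def toy_table() -> CountTable:
    """Six-sample, five-feature integer table with two groups."""
    counts = pd.DataFrame(
        {
            "t1": [10, 0, 5, 3, 2],
            "t2": [12, 1, 4, 3, 0],
            "t3": [9, 0, 6, 4, 1],
            "s1": [2, 8, 5, 3, 2],
            "s2": [1, 9, 4, 5, 1],
            "s3": [3, 7, 6, 2, 2],
        },
        index=[f"f{i}" for i in range(5)],
    )
    groups = {s: ("thrombolite" if s.startswith("t") else "sediment") for s in counts}
    return CountTable(counts=counts, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140201)  # field-survey date
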