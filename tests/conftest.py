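import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from drivernet.io import ExpressionMatrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """5 genes x 4 samples, two conditions, no missing values."""
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 2.5, 3.5, 4.5],
                [9.0, 8.0, 7.0, 6.0],
                [1.1, 2.1, 3.1, 4.1],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
        index=[f"g{i}" for i in range(5)],
        columns=["s1", "s2", "s3", "s4"],
    )
    design = pd.Series(
        {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}, name="condition"
    )
    return ExpressionMatrix(values=values, design=design)
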