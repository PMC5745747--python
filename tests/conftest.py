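import numpy as np
import pandas as pd
import pytest

from xplatsig import ExpressionMatrix, Signature


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, two HP and two SSA/P."""
    data = pd.DataFrame(
        [[1.0, 2.0, 5.0, 6.0],
         [4.0, 3.0, 1.0, 0.0],
         [2.0, 2.5, 2.0, 2.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series(["HP", "HP", "SSA/P", "SSA/P"], index=data.columns)
    return ExpressionMatrix(data, labels, platform="toy")


@pytest.fixture
def toy_signature():
    return Signature(["g1", "g2"], [1, -1])
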