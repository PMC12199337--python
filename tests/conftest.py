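import numpy as np
import pytest

from tfactnet.datamodel import GeneExpressionMatrix


@pytest.fixture
def small_expr() -> GeneExpressionMatrix:
    """3 genes x 2 cells with simple counts."""
    return GeneExpressionMatrix(
        np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]]),
        ["g1", "g2", "g3"],
        ["c1", "c2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
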