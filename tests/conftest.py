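import numpy as np
import pytest

from ggat import LabeledExpressionMatrix


@pytest.fixture
def toy_matrix() -> LabeledExpressionMatrix:
    """4 samples x 3 genes, two classes, small integer counts."""
    return LabeledExpressionMatrix(
        sample_ids=["s0", "s1", "s2", "s3"],
        gene_ids=["g0", "g1", "g2"],
        values=np.array(
            [[1.0, 4.0, 10.0], [2.0, 5.0, 12.0], [8.0, 1.0, 11.0], [9.0, 2.0, 9.0]]
        ),
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
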