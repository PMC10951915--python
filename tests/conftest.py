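import numpy as np
import pandas as pd
import pytest

from embryoprot.io import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 entities x 2 stages, no missing values."""
    df = pd.DataFrame(
        {"unfE": [1.0, 2.0, 3.0], "larva": [4.0, 5.0, 6.0]},
        index=pd.Index(["g1", "g2", "g3"], name="entity_id"),
    )
    return ExpressionMatrix(df, modality="protein_relative", species="ciona")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240229)
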