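import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from appsig.data_io import ClassLabels, ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, linear scale, hand-checkable values."""
    values = pd.DataFrame(
        [[2.0, 4.0, 8.0, 16.0], [1.0, 2.0, 4.0, 8.0], [3.0, 6.0, 12.0, 24.0]],
        index=["g1", "g2", "g3"],
        columns=["PA01", "PA02", "GA01", "GA02"],
    )
    return ExpressionMatrix(values, scale="linear")


@pytest.fixture
def tiny_labels(tiny_matrix) -> ClassLabels:
    return ClassLabels(
        pd.Series([0, 0, 1, 1], index=tiny_matrix.sample_ids, name="class_code")
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210608)
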