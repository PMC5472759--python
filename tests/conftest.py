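import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rccpipe import ExpressionMatrix

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.poisson(50, size=(50, 4)).astype(float),
        index=[f"g{i:02d}" for i in range(50)],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, "counts")


@pytest.fixture
def small_log2() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.normal(5, 1, size=(30, 6)),
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data, "log2")
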