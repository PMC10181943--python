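import numpy as np
import pandas as pd
import pytest

from icbscreen.io import ExpressionMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """4 genes x 6 samples, deterministic values."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.5, 8.0, size=(4, 6))
    return ExpressionMatrix(
        [f"G{i}" for i in range(4)], [f"S{j}" for j in range(6)], values
    )


@pytest.fixture
def two_group_expr() -> tuple[ExpressionMatrix, pd.Series]:
    """20 genes x 20 samples; gene G0 shifted +2 in responders."""
    rng = np.random.default_rng(7)
    values = rng.normal(4.0, 0.1, size=(20, 20)).clip(0)
    response = pd.Series(
        [1] * 10 + [0] * 10, index=[f"S{j:02d}" for j in range(20)]
    )
    values[0, :10] += 2.0
    expr = ExpressionMatrix(
        [f"G{i}" for i in range(20)], list(response.index), values
    )
    return expr, response
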