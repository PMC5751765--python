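import numpy as np
import pytest

from twodem import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """6 samples x 5 features with two obvious sample groups."""
    rng = np.random.default_rng(42)
    base = rng.normal(0, 1, size=(6, 5))
    base[3:] += 10.0
    return ExpressionMatrix(
        base,
        sample_ids=[f"S{i}" for i in range(6)],
        feature_ids=[f"F{j}" for j in range(5)],
    )
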