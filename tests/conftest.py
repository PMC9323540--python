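import numpy as np
import pytest

from ilqspr.io import CationRecord, PropertySeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_series():
    """Three cations with easy logK ordering."""
    return PropertySeries(
        solute="hexane",
        records=(
            CationRecord("[A]+", "CC[N+](C)(C)C", 0.5),
            CationRecord("[B]+", "CCn1cc[n+](C)c1", 1.2),
            CationRecord("[C]+", "CC[n+]1ccccc1", 0.9),
        ),
    )


def ols_oracle(X, y):
    """Normal-equation coefficients (β₀ first), computed independently."""
    D = np.hstack([np.ones((X.shape[0], 1)), X])
    return np.linalg.solve(D.T @ D, D.T @ y)
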