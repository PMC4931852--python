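import numpy as np
import pandas as pd
import pytest

from swabage.io import BetaMatrix
from swabage.synthetic import reference_cell_types


@pytest.fixture(scope="session")
def cell_types():
    """Default leukocyte/epithelial specs, consistent with the 5-CpG clock."""
    return reference_cell_types()


@pytest.fixture
def small_matrix():
    """3 samples x 5 probes, fully observed, with ages."""
    values = pd.DataFrame(
        {
            "cg0001": [0.1, 0.5, 0.9],
            "cg0002": [0.0, 0.25, 1.0],
            "cg0003": [0.3, 0.3, 0.3],
            "cg0004": [0.7, 0.2, 0.4],
            "cg0005": [0.05, 0.95, 0.5],
        },
        index=["A", "B", "C"],
    )
    ages = pd.Series([10.0, 40.0, 70.0], index=values.index)
    return BetaMatrix(values, ages=ages)


def ols_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent normal-equations least squares: (X'X)^-1 X'y."""
    XtX = X.T @ X
    return np.linalg.inv(XtX) @ (X.T @ y)
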