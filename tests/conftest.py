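import numpy as np
import pandas as pd
import pytest

from targetgene.expression import CASE, CONTROL, ExpressionStudy


def make_study(values, n_cases, n_controls, study_id="S1", genes=None):
    """ExpressionStudy from an array; first n_cases columns are cases."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = [f"{study_id}_{j + 1}" for j in range(arr.shape[1])]
    labels = pd.Series(
        [CASE] * n_cases + [CONTROL] * n_controls, index=samples
    )
    return ExpressionStudy(
        study_id, pd.DataFrame(arr, index=genes, columns=samples), labels
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
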