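import numpy as np
import pandas as pd
import pytest

from immunosig.preprocess import SCALE_LOG, ExpressionMatrix


def make_matrix(values, genes=None, samples=None, scale=SCALE_LOG) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    return make_matrix(rng.normal(5, 1, size=(6, 10)))
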