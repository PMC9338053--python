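from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tfnet.datatypes import ExpressionMatrix


def make_expression(values: np.ndarray, genes=None, samples=None, conditions=None) -> ExpressionMatrix:
    """Wrap a raw matrix in a valid ExpressionMatrix with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    conditions = conditions or ["c"] * n_samples
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "timepoint": 1,
            "replicate": np.arange(n_samples) + 1,
        },
        index=samples,
    )
    return ExpressionMatrix(genes, samples, values, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
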