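import numpy as np
import pytest

from metacci.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, genes=None, cells=None, labels=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    genes = genes or [f"g{i}" for i in range(p)]
    cells = cells or [f"c{i}" for i in range(n)]
    labels = labels if labels is not None else ["grp"] * n
    return ExpressionMatrix(values, genes, cells, np.array(labels, dtype=object))


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.uniform(0, 10, size=(12, 4)))
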