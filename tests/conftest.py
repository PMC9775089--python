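import numpy as np
import pytest

from grnpipe.expression import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expr(values, genes=None, groups=None):
    """Wrap a raw array as an ExpressionMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    genes = genes or [f"G{i + 1:03d}" for i in range(p)]
    samples = [f"S{j + 1:03d}" for j in range(n)]
    groups = groups or ["case"] * (n // 2) + ["control"] * (n - n // 2)
    return ExpressionMatrix(genes, samples, values, groups)


@pytest.fixture
def expr_factory():
    return make_expr
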