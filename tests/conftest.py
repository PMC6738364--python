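import numpy as np
import pytest

from cidnet.core import ExpressionMatrix, KernelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def degenerate_cfg():
    return KernelConfig(degenerate_limit=True)


@pytest.fixture
def small_matrix(rng):
    """A 6-probe x 30-sample matrix with one strong dependency (P1 -> P2)."""
    n = 30
    p1 = rng.normal(1.0, 1.0, n)
    p2 = np.where(p1 > 0, p1 + rng.normal(0, 0.25, n),
                  rng.normal(-1.0, 0.25, n))
    rest = rng.normal(0.0, 1.0, (4, n))
    values = np.vstack([p1, p2, rest])
    return ExpressionMatrix([f"P{i + 1}" for i in range(6)],
                            [f"s{j + 1}" for j in range(n)], values)
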