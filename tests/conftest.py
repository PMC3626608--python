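import numpy as np
import pytest

from arrayqc import ExpressionMatrix, SimulationConfig, generate


def make_matrix(values, prefix_f="f", prefix_s="s", **kw):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return ExpressionMatrix(
        values,
        [f"{prefix_f}{i}" for i in range(p)],
        [f"{prefix_s}{j}" for j in range(n)],
        **kw,
    )


@pytest.fixture
def tiny_matrix():
    """The 3 x 2 worked example: columns (1,2,3) and (3,4,5)."""
    return make_matrix([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]])


@pytest.fixture
def clean_synthetic():
    """A small clean (no outliers) synthetic experiment."""
    em, truth = generate(SimulationConfig(p=800, n=12, seed=11))
    return em, truth


@pytest.fixture
def gaussian_matrix():
    """Quality-heterogeneous Gaussian data with one high-noise array (index 5)."""
    rng = np.random.default_rng(0)
    p, n = 2000, 20
    scales = np.exp(rng.normal(0, 0.25, n))
    scales[5] = 3.0
    X = rng.normal(8, 1, (p, 1)) + scales[None, :] * rng.normal(0, 0.5, (p, n))
    return make_matrix(X), 5
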