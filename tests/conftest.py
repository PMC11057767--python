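import numpy as np
import pytest

from bqridge import RegressionData, generate_design, generate_true_coefficients


@pytest.fixture
def rng():
    return np.random.default_rng(20240429)


def make_collinear_data(
    n: int = 30,
    p: int = 4,
    rho: float = 0.9,
    sigma: float = 0.7,
    seed: int = 0,
) -> RegressionData:
    """Seeded collinear regression dataset with known-structure truth."""
    rng = np.random.default_rng(seed)
    X = generate_design(n, p, rho, rng)
    tm = generate_true_coefficients(X)
    y = X @ tm.beta_true + sigma * rng.standard_normal(n)
    return RegressionData(X=X, y=y)


@pytest.fixture
def collinear_data():
    return make_collinear_data()
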