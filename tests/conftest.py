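import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def small_signature():
    """Well-conditioned 60-gene, 3-type block-marker signature."""
    from fardeep.simulate import make_synthetic_signature

    return make_synthetic_signature(n_genes=60, p=3, markers_per_type=15, seed=11)


@pytest.fixture()
def regression_instance():
    """Moderate correlated-design problem with 10% planted outliers."""
    from fardeep.simulate import RegressionSimConfig, simulate_regression

    return simulate_regression(
        RegressionSimConfig(n=120, p=5, outlier_frac=0.10, seed=42)
    )


def random_nonneg_problem(rng: np.random.Generator, n: int, p: int):
    """Small NNLS problem with non-negative design and mixed-sign response."""
    X = rng.uniform(0, 5, size=(n, p))
    y = X @ rng.uniform(0, 2, size=p) + rng.normal(0, 2, size=n)
    return X, y
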