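import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_benchmark():
    """A 6-plot benchmark realization shared by pipeline-level tests."""
    from ricepam.synthetic import generate_benchmark

    return generate_benchmark(n_plots=6, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
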