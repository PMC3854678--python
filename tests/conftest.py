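import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20130)


@pytest.fixture
def random_matrix_game(rng):
    from selrank import MatrixGame

    def make(n=3, dist="uniform", seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        if dist == "uniform":
            return MatrixGame(r.uniform(size=(n, n)))
        return MatrixGame(r.standard_normal((n, n)))

    return make
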