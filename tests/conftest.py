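import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def small_association_data(rng):
    """n=50, k=1 dataset with a genuine genotype-phenotype association."""
    from scipy.special import expit

    x = rng.normal(size=(50, 1))
    p = expit(-1.0 + 0.5 * x[:, 0])
    counts = rng.binomial(2, p)
    if counts.sum() in (0, 100):  # pragma: no cover - effectively impossible
        counts[0] = 1
    return x, counts
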