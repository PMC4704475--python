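import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


@pytest.fixture()
def trait_data(rng):
    """A 100-subject, 5-trait dataset with moderate correlation and signal."""
    import fcgwas as fg

    x = fg.simulate_genotype(100, 0.25, rng)
    while not x.is_polymorphic:
        x = fg.simulate_genotype(100, 0.25, rng)
    Y = fg.simulate_phenotypes(x, [0.3] * 5, 0.5, rng)
    return Y, x
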