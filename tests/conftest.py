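import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-phase dataset shared by read-only tests."""
    from pirnakit.synth import SimConfig, simulate_dataset

    cfg = SimConfig(seed=7, n_chroms=2, chrom_length=300_000, n_clusters=10)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
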