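import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diauxie.experiments import ProtocolConfig, ce_violation_sweep, diversity_scaling
from diauxie.pools import PoolSpec, sample_pool

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pool():
    return sample_pool(PoolSpec(n_resources=3, n_species=8, seed=5))


@pytest.fixture(scope="session")
def sweep_results():
    """Scaled competitive-exclusion sweep: 20 pools x 300 species x 1e4 cycles.

    Pools include anomalous species (independent random preferences) and are
    reused at both fluctuation magnitudes, mirroring the full-scale design.
    """
    pools = [sample_pool(PoolSpec(3, 300, seed=j)) for j in range(20)]
    summary, reports = ce_violation_sweep(
        pools, [0.0, 0.15], seed=101, config=ProtocolConfig(n_cycles=10_000)
    )
    return pools, summary, reports


@pytest.fixture(scope="session")
def scaling_results():
    """Diversity scaling on 2-5 resources, uniform-random supply, 5 pools each.

    Runs are long enough (1e5 cycles) that survivor sets are converged; pool
    sizes follow the density rule up to a budget cap of 1000 species.
    """
    return diversity_scaling(
        [2, 3, 4, 5],
        n_pools=5,
        seed=202,
        config=ProtocolConfig(n_cycles=100_000),
        pool_cap=1000,
    )
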