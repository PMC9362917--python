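import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import csdtrflp as c

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return c.AlleleTemplate()


@pytest.fixture(scope="session")
def reference_allele(template):
    return c.make_allele(template, [], "ref")


@pytest.fixture(scope="session")
def allele_pool():
    rng = np.random.default_rng(20220809)
    return c.make_allele_pool(30, rng)


@pytest.fixture()
def quiet_colony(allele_pool):
    """Noise-free colony with unique drone alleles and no lethality
    (queen-identical drone alleles are excluded by uniqueness)."""
    rng = np.random.default_rng(11)
    cfg = c.ColonySimConfig(n_drones=10, allele_pool_size=30, n_workers=240,
                            unique_drone_alleles=True, trflp_noise_sd=0.0,
                            rng_seed=11)
    return c.simulate_colony(cfg, allele_pool, rng, colony_id="colA")
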