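"""Shared fixtures: small seeded synthetic populations for fast tests."""

import numpy as np
import pytest

from hlamatch.simulate import GeneratorConfig, generate_cohort, generate_pools, generate_registry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        afr_pool_size=80,
        eur_pool_size=30,
        registry_size=400,
        cohort_size=60,
        scd_size=10,
        n_snps=300,
        calibration_size=2000,
        self_id_sigma=0.16,  # fixed: skip calibration in small fixtures
    )


@pytest.fixture(scope="session")
def small_pools(small_config):
    return generate_pools(small_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_registry(small_config, small_pools):
    return generate_registry(small_config, small_pools, np.random.default_rng(8))


@pytest.fixture(scope="session")
def small_cohort(small_config, small_pools):
    return generate_cohort(
        small_config, small_pools, 30, "merged", np.random.default_rng(9), sigma=0.16
    )
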