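import numpy as np
import pandas as pd
import pytest

from alongtract.synthetic import SimulationConfig, Site, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_subjects=120, n_tracts=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(cohort, atlas, endpoint_table, profiles, truth) for a small cohort."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def two_site_config() -> SimulationConfig:
    return SimulationConfig(
        n_subjects=160,
        n_tracts=2,
        sites=(Site("siteA", 0.0, 1.0), Site("siteB", 0.04, 1.3)),
        seed=21,
    )


def make_cohort(n: int, seed: int = 0, age_min: float = 8.0, age_max: float = 23.0) -> pd.DataFrame:
    """Plain covariate table for unit tests that bypass the generator."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i:04d}" for i in range(n)],
            "age": rng.uniform(age_min, age_max, n),
            "sex": rng.integers(0, 2, n),
            "motion": rng.uniform(0.05, 0.6, n),
            "site": "site0",
        }
    )
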