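import logging

import numpy as np
import pandas as pd
import pytest

from myconet.core import HABITATS, AsvTable
from myconet.simulate import SyntheticSpec, generate

# the vacuous-KLD warning is intentional and noisy in test output
logging.getLogger("myconet.inference").setLevel(logging.ERROR)


@pytest.fixture
def toy_table() -> AsvTable:
    """3 samples x 4 ASVs with hand-chosen counts."""
    return AsvTable(
        pd.DataFrame(
            {
                "a1": [10, 0, 5],
                "a2": [0, 3, 5],
                "a3": [1, 1, 1],
                "a4": [0, 0, 2],
            },
            index=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "habitat": list(HABITATS),
            "latitude": [29.0, 30.0, 31.0],
            "longitude": [85.0, 85.5, 86.0],
        }
    )


def planted_spec(**overrides) -> SyntheticSpec:
    """Spec that isolates the planted copula: no spatial turnover, uniform
    occupancy, so the only inter-taxon correlations are the planted ones."""
    params = dict(
        sample_scale=100 / 92,
        n_asvs=80,
        n_modules=4,
        module_size=10,
        within_module_rho=0.8,
        spatial_decay_rate=0.0,
        base_occupancy=1.0,
        richness_effect=(1.0, 1.0, 1.0),
        seed=7,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture(scope="session")
def planted_data():
    return generate(planted_spec())


@pytest.fixture(scope="session")
def default_data():
    """Generator with all default realism features on (spatial gradient,
    habitat occupancy, negative edges)."""
    return generate(SyntheticSpec(sample_scale=0.5, n_asvs=150, seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
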