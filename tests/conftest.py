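import numpy as np
import pandas as pd
import pytest

from crossreg.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-sized configuration shared by fast tests."""
    return SimulationConfig(
        seed=42,
        n_genes=400,
        n_probes=3000,
        dm_region_count=30,
        n_tss=400,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def toy_beta(values_by_sample: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(values_by_sample)
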