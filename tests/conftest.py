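import numpy as np
import pandas as pd
import pytest

from refstab import SimulationConfig, simulate_compendium


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    """Two replicate groups per partition style, 4 samples."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "study_id": ["st1", "st1", "st2", "st2"],
            "replicate_group": ["leaf", "leaf", "root_cold", "root_cold"],
            "partition": ["development", "development", "abiotic", "abiotic"],
        }
    )


@pytest.fixture
def small_expression(small_metadata) -> pd.DataFrame:
    rng = np.random.default_rng(7)
    values = rng.uniform(100, 10000, size=(3, 4))
    return pd.DataFrame(
        values,
        index=pd.Index(["g1", "g2", "g3"], name="probeset_id"),
        columns=list(small_metadata["sample_id"]),
    )


@pytest.fixture(scope="session")
def tiny_compendium():
    """A 40-gene simulated compendium shared across tests (read-only)."""
    return simulate_compendium(SimulationConfig(n_genes=40, seed=11))
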