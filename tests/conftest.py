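import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from isospec.data import IsotopeDataset
from isospec.simulate import SimulationConfig, generate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> pd.DataFrame:
    """2 individuals × 2 tissues, hand-sized."""
    return pd.DataFrame({
        "individual_id": ["U1", "U1", "U2", "U2"],
        "site": ["Uatuma"] * 4,
        "tissue": ["muscle", "fin", "muscle", "fin"],
        "standard_length": [31.0, 31.0, 42.5, 42.5],
        "total_weight": [800.0, 800.0, 1900.0, 1900.0],
        "d13C": [-35.2, -30.1, -37.0, -31.8],
        "d15N": [14.1, 13.9, 14.8, 14.2],
        "cn_ratio": [3.1, 3.2, 3.0, 3.1],
    })


@pytest.fixture
def tiny_dataset(tiny_table) -> IsotopeDataset:
    return IsotopeDataset(tiny_table)


@pytest.fixture(scope="session")
def default_study():
    """Full default synthetic study (two sites, 27/21 individuals)."""
    return generate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def recovery_study():
    """Single-site 30-individual study used for parameter-recovery checks."""
    cfg = SimulationConfig(sites=("S1",), n_individuals_per_site=(30,),
                           fin_dropout=(0.0,), baseline_d15N=(5.31,), seed=11)
    return cfg, generate_study(cfg)
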