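import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from arboreml import ProgenyTrialData, SimulationConfig, simulate

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CONFIG = SimulationConfig(
    trial_grids={"A": (1, 15, 12), "B": (2, 12, 15)},
    n_blocks=6,
    n_families_series1=12,
    n_families_series2=12,
    n_shared_families=8,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-trial synthetic dataset small enough for many refits."""
    return simulate(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_data(small_dataset) -> ProgenyTrialData:
    return small_dataset.data()


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture()
def grid_records():
    """Fully stocked 4x4 single-trial record table."""
    rows, cols = np.meshgrid(np.arange(1, 5), np.arange(1, 5), indexing="ij")
    return pd.DataFrame(
        {
            "trial": "T1",
            "row": rows.ravel(),
            "col": cols.ravel(),
            "tree_id": [f"t{i}" for i in range(16)],
            "rep": "B1",
        }
    )
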