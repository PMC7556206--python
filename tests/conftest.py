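import numpy as np
import pytest

from hfoasym.config import SimulationConfig
from hfoasym.fixtures import load_fixture
from hfoasym.simulate import pink_noise


@pytest.fixture(scope="session")
def table2_cohort():
    """The packaged 16-patient cohort table (patient_id, true_group, r_fr)."""
    return load_fixture("table2")[["patient_id", "true_group", "r_fr"]].copy()


@pytest.fixture(scope="session")
def mini_config():
    """A small, fast simulation configuration used across tests."""
    return SimulationConfig(
        n_patients=3, group_counts=(1, 1, 1), cohort_channel_totals=(6, 9),
        segment_duration=60.0, seed=11,
    )


@pytest.fixture()
def noise_60s():
    """60 s of seeded pink background noise at the default recording setup."""
    rng = np.random.default_rng(42)
    return pink_noise(120_000, 2000.0, 1.0, 25.0, 800.0, rng)
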