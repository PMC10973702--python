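import numpy as np
import pytest

from sulcalml import SimulationConfig, apply_exclusions, simulate_table


@pytest.fixture(scope="session")
def clean_table():
    """Small preprocessed cohort with two planted effects, no contamination."""
    cfg = SimulationConfig(
        n_per_class=40,
        n_regions=10,
        heavy_tail_fraction=0.0,
        effect_features=[(0, 1.2), (7, 1.0)],
        seed=11,
    )
    table, _ = apply_exclusions(simulate_table(cfg))
    return table


@pytest.fixture(scope="session")
def null_table():
    """Cohort with no group differences at all (for calibration checks)."""
    cfg = SimulationConfig(
        n_per_class=57, n_regions=49, heavy_tail_fraction=0.0, seed=29
    )
    table, _ = apply_exclusions(simulate_table(cfg))
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
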