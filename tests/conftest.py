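import numpy as np
import pytest

from photocycle import SimulationConfig, generate_cohort
from photocycle.preprocess import CompletedSeries


def make_series(bbt) -> CompletedSeries:
    """Wrap a raw temperature list (NaN = unavailable) as a CompletedSeries."""
    bbt = np.asarray(bbt, dtype=float)
    observed = ~np.isnan(bbt)
    return CompletedSeries(
        day_index=np.arange(1, len(bbt) + 1),
        bbt=bbt,
        observed_mask=observed,
        imputed_mask=np.zeros(len(bbt), dtype=bool),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-user default-parameter cohort shared across tests."""
    cfg = SimulationConfig(n_users=200, seed=7)
    users, cycles, daily, truth = generate_cohort(cfg)
    return cfg, users, cycles, daily, truth
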