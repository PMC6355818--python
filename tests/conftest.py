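import numpy as np
import pytest

from dupmode import SimConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulated scenario (12 events, 4 per mechanism, seed 42)."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def retro_only_dataset():
    """Five retroduplications at zero divergence: clean flank signatures."""
    return simulate(SimConfig(seed=7, n_events=5, event_type_counts=(0, 0, 5),
                              subs_rate_per_site_per_step=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
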