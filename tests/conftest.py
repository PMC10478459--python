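import numpy as np
import pytest

from mgblup.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 lines x 2 environments x 3 replicates, 30 features (~132 plots)."""
    cfg = SimulationConfig(
        n_lines=20, n_markers=80, n_features=30,
        years=("Y1", "Y2"), locations=("A",),
        lines_per_trial=(8, 12), envs_per_line=None,
        plots_per_batch=10, seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
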