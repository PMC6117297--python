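import numpy as np
import pytest

from labelkin.simcore import SimConfig, simulate_pulse_chase


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def week0_cohort():
    """Small freshly-labeled cohort (no chase divisions) with ground truth."""
    cfg = SimConfig(n_mice_per_group=2, n_cells_per_mouse=500,
                    chase_weeks=(0.0,), max_population=5000, seed=11)
    events, truth = simulate_pulse_chase(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def chase_cohort():
    """Transgenic-only cohort sampled at a 2-week chase."""
    cfg = SimConfig(groups=("lmo2",), n_mice_per_group=2,
                    n_cells_per_mouse=800, chase_weeks=(2.0,),
                    max_population=8000, seed=21)
    events, truth = simulate_pulse_chase(cfg)
    return cfg, events, truth
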