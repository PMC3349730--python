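import numpy as np
import pytest

from repkin.model import ChromosomeModel, Origin, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_origin_chrom():
    """100 kb chromosome with origins at both ends firing 10 and 20 min."""
    return ChromosomeModel(
        name="chrT",
        length=100_000,
        origins=(
            Origin("oriA", 0, 10.0, firing_sd=0.0, efficiency=1.0),
            Origin("oriB", 100_000, 20.0, firing_sd=0.0, efficiency=1.0),
        ),
    )


@pytest.fixture
def deterministic_params():
    """No cell-to-cell variability: every cell enters at 40 min, all origins fire."""
    return SimulationParams(
        fork_velocity=1500.0,
        s_entry_mean=40.0,
        s_entry_sd=0.0,
        fraction_cycling=1.0,
        n_cells=50,
        seed=0,
    )
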