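import numpy as np
import pytest

from quiet2p import scan_optics as so
from quiet2p import stimuli as st
from quiet2p import synth_imaging as si


@pytest.fixture
def aod():
    return so.AODSpec()


@pytest.fixture
def relay():
    return so.RelaySpec()


@pytest.fixture
def small_grid():
    """5 frequencies x 3 levels, same timing as the standard grid."""
    return st.make_fra_grid(n_freqs=5, level_lo=5.0, level_hi=65.0,
                            level_step=30.0)


@pytest.fixture(scope="session")
def tiny_session():
    """A small rendered session with motion and noise, shared across tests.

    5 x 3 grid, 3 cycles (45 trials), 48 x 48 px at 10 fps, 8 neurons.
    """
    grid = st.make_fra_grid(n_freqs=5, level_lo=5.0, level_hi=65.0,
                            level_step=30.0)
    schedule = st.make_session_schedule(grid, cycles=3, seed=2)
    config = si.SimConfig(frame_shape=(48, 48), frame_rate=10.0,
                          n_neurons=8, soma_radius_px=2.5, seed=3)
    population = si.make_population(config, grid)
    session = si.render_session(population, config, schedule, grid)
    return dict(grid=grid, schedule=schedule, config=config,
                population=population, session=session)
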