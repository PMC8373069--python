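import numpy as np
import pytest

from smber import SimulationConfig, Trajectory, fit_standard_curve


@pytest.fixture
def rng():
    return np.random.default_rng(20210707)


@pytest.fixture
def standard_curve():
    # synthetic calibration points (placeholder masses, not literature values)
    return fit_standard_curve([
        ("standard_A", 100.0, 125.0),
        ("standard_B", 200.0, 245.0),
        ("standard_C", 320.0, 390.0),
    ])


def make_trajectory(positions, dt=0.08, particle_id=0, channel="605", censored=False):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(positions.size) * dt
    return Trajectory(particle_id, channel, times, positions, censored=censored)


@pytest.fixture
def short_window_config():
    """300-frame observation window at 12.5 fps, all particles motile."""
    def _make(**overrides):
        kwargs = dict(n_particles=50, motile_fraction=1.0, loc_noise_sd=0.0,
                      window=24.0, half_life_true=1e9, seed=11)
        kwargs.update(overrides)
        return SimulationConfig(**kwargs)
    return _make
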