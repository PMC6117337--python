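import numpy as np
import pytest

from microstim import (Resistivities, SimulationConfig, StimulusWaveform,
                       SurrogateModel, get_engine, surrogate_grid)


@pytest.fixture(scope="session")
def rho():
    return Resistivities()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def waveform():
    return StimulusWaveform(cathodic_amplitude=10.0)


@pytest.fixture(scope="session")
def engine10():
    """Shared 10 µm-fiber threshold engine (memoized across tests)."""
    return get_engine(10.0)


@pytest.fixture(scope="session")
def iso_surrogate():
    """Isotropic single-electrode surrogate: t = 1 + 1e-4·r² µA."""
    return SurrogateModel(k=1e-4, offset=1.0, weights=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def aniso_pair_surrogate():
    """Anisotropic two-electrode surrogate, co-located pair (analytic
    volume ratio available in closed form)."""
    return SurrogateModel(k=2e-4, offset=2.0, weights=(1.0, 1.0, 0.25),
                          electrodes=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)))


def make_random_field(seed, shape=(5, 4, 6), step=(20.0, 20.0, 10.0),
                      nan_frac=0.0, z_period=None):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1.0, 30.0, size=shape)
    if nan_frac > 0:
        mask = rng.random(shape) < nan_frac
        vals[mask] = np.nan
    model = SurrogateModel()
    f = surrogate_grid(model, (0.0, 0.0, 0.0), shape, step)
    f.values = vals
    f.z_period = z_period
    return f
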