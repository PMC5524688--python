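import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from geminate.dse_core import MediumContext, bound_population
from geminate.signal_model import EmissionCurve, gaussian_irf
from geminate.synthetic_data import (DEFAULT_CHANNEL_WIDTH, DEFAULT_N_CHANNELS,
                                     make_tcspc, photoacid_registry)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

TAU_ROH = 8.0


@pytest.fixture(scope="session")
def medium():
    return MediumContext()


@pytest.fixture(scope="session")
def registry():
    return photoacid_registry()


@pytest.fixture(scope="session")
def channels():
    return np.arange(DEFAULT_N_CHANNELS) * DEFAULT_CHANNEL_WIDTH


@pytest.fixture(scope="session")
def irf(channels):
    return gaussian_irf(1.0, 2.0, DEFAULT_CHANNEL_WIDTH, DEFAULT_N_CHANNELS)


@pytest.fixture(scope="session")
def decay_factory(channels, irf):
    """Synthesize a TCSPC histogram from a solver configuration.

    Noiseless histograms default to a high peak so integer rounding does
    not swallow the power-law tail the fits rely on.
    """
    cache = {}

    def make(cfg, peak=1e9, noise=False, seed=1, background=0.0):
        key = (cfg, peak, noise, seed, background)
        if key not in cache:
            p = bound_population(cfg, channels)
            curve = EmissionCurve(times=channels,
                                  intensity=p * np.exp(-channels / TAU_ROH))
            cache[key] = make_tcspc(curve, irf, peak_counts=peak,
                                    background=background, seed=seed, noise=noise)
        return cache[key]

    return make
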