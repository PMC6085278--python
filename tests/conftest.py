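"""Shared fixtures: simulated data reused across test modules."""

import numpy as np
import pytest

from neuroassim import models
from neuroassim.params import ELLIPTIC, HOMOCLINIC, HOPF, SNIC, SQUARE_WAVE

REGIMES = {
    "HOPF": HOPF,
    "SNIC": SNIC,
    "HOMO": HOMOCLINIC,
    "square-wave": SQUARE_WAVE,
    "elliptic": ELLIPTIC,
}


@pytest.fixture(scope="session")
def spiking_trajectories():
    """Full 20 s noiseless trajectories for the three spiking regimes."""
    return {
        name: models.simulate(REGIMES[name], t_end=20000.0, dt=0.1)
        for name in ("HOPF", "SNIC", "HOMO")
    }


@pytest.fixture(scope="session")
def snic_series(spiking_trajectories):
    """Noisy SNIC observations used by several estimator tests."""
    return models.observe_with_noise(spiking_trajectories["SNIC"], 0.01, seed=7)


@pytest.fixture(scope="session")
def short_snic_series():
    """200 ms noisy SNIC observations (variational-method window)."""
    traj = models.simulate(SNIC, t_end=200.0, dt=0.1)
    return traj, models.observe_with_noise(traj, 0.01, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
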