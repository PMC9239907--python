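import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from mmsurv.synthetic import SimulationConfig, simulate_cohort


def random_survival(rng, n, censor_frac=0.3, beta=0.0):
    """Small random censored survival instance (continuous times, no ties)."""
    x = rng.normal(size=n)
    T = rng.exponential(scale=50.0, size=n) * np.exp(-beta * x)
    E = rng.random(n) > censor_frac
    return x, T, E


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multimodal cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_patients=250,
        n_features={"radiomic": 40, "histopathology": 30},
        seed=11,
    )
    return simulate_cohort(cfg)
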