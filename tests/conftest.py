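import numpy as np
import pandas as pd
import pytest

from thermassembly.environment import EnvironmentConfig, ProductivityModel
from thermassembly.simulator import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_config():
    """A small, fast simulation configuration for smoke-level tests."""
    return SimulationConfig(
        env=EnvironmentConfig(t_mean=18.0, sigma_short=2.5, sigma_long=0.0),
        prod=ProductivityModel(),
        n_steps=2000,
        seed=7,
    )


@pytest.fixture
def gaussian_cloud_table(rng):
    """Standard bivariate normal points posing as standardized traits."""
    n = 10_000
    pts = rng.normal(size=(n, 2))
    return pd.DataFrame(
        {
            "species": [f"s{i}" for i in range(n)],
            "ctmin_c": pts[:, 0],
            "ctmax_c": pts[:, 0] + 10.0,
            "n": 1.0,
            "ctmin_z": pts[:, 0],
            "ctmax_z": pts[:, 1],
        }
    )


def make_trait_table(ctmin, ctmax, n=None, site=""):
    ctmin = np.asarray(ctmin, dtype=float)
    ctmax = np.asarray(ctmax, dtype=float)
    if n is None:
        n = np.ones(ctmin.size)
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(ctmin.size)],
            "ctmin_c": ctmin,
            "ctmax_c": ctmax,
            "n": np.asarray(n),
            "site": site,
        }
    )
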