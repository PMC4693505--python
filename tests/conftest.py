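import numpy as np
import pandas as pd
import pytest

from methlink.simulate import SimulationConfig, simulate_study


SMALL_CONFIG = dict(
    seed=7,
    n_probes=2000,
    n_planted_dm=200,
    n_genes=500,
    n_planted_deg=50,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across tests (same planted geometry
    as the defaults, scaled down)."""
    return simulate_study(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def tiny_beta():
    """4 probes x 4 samples beta matrix with one missing value."""
    return pd.DataFrame(
        {
            "s1": [0.1, 0.9, 0.5, np.nan],
            "s2": [0.2, 0.8, 0.5, 0.4],
            "s3": [0.15, 0.85, 0.5, 0.6],
            "s4": [0.05, 0.95, 0.5, 0.5],
        },
        index=[f"cg{i}" for i in range(4)],
    )
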