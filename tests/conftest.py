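import warnings

import numpy as np
import pandas as pd
import pytest

from phenosense.simulate import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic monitoring dataset."""
    cfg = SimulationConfig(
        n_sites=4, n_species=6, year_start=2004, year_end=2019, seed=101
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def flat_temperature():
    """Constant 10 degC monthly series for two sites, 2000-2010."""
    rows = [
        dict(site_id=s, year=y, month=m, tmin=5.0, tmean=10.0, tmax=15.0)
        for s in ("a", "b")
        for y in range(1999, 2011)
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
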