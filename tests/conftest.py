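import numpy as np
import pytest

import zfbattery as z


@pytest.fixture(scope="session")
def small_plate() -> z.PlateDataset:
    """A 12-well plate (6 wt, 6 hom) with the default compressed stimulus
    battery, shared across tests that only read it."""
    cfg = z.SimConfig(seed=7, n_per_genotype={"wt": 6, "hom": 6}, duration_s=120.0)
    return z.simulate_plate(cfg)


@pytest.fixture
def geometry() -> z.WellGeometry:
    return z.WellGeometry(side_px=200.0)


@pytest.fixture
def bout_params() -> z.BoutParams:
    return z.BoutParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
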