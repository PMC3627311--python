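import numpy as np
import pytest
from hypothesis import settings

import nirschange as nc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage() -> nc.Montage:
    return nc.build_montage()


@pytest.fixture(scope="session")
def montage_long() -> nc.Montage:
    return nc.build_montage(include_long=True)


@pytest.fixture(scope="session")
def small_schedule() -> nc.Schedule:
    """Eight-target infant session, fixed seed."""
    return nc.generate_infant_schedule(nc.ScheduleConfig(n_target_blocks=8, seed=7))


@pytest.fixture(scope="session")
def silent_noise() -> nc.NoiseModel:
    return nc.NoiseModel.silent()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
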