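import numpy as np
import pytest
from hypothesis import settings

from ecovuln.synthetic import DriverSpec, LandscapeSpec, default_driver_spec, generate_driver_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_landscape():
    return LandscapeSpec(
        n_rows=20, n_cols=20,
        conversion_fraction=0.1,
        years=tuple(range(1983, 2023)),
        seed=1,
    )


@pytest.fixture(scope="session")
def driver_table():
    """Default driver table (planted GI/SM/VPD/PRE effects, physical
    collinearity), 2000 samples."""
    spec = default_driver_spec()
    X, y, truth = generate_driver_table(spec, 2000, seed=11)
    return X, y, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
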