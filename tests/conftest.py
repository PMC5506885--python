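import numpy as np
import pytest

import ukftract as u

# Small grids keep the unit suite fast; full-size study conditions are
# exercised in test_acceptance.py.
TINY = dict(dims_mm=(60.0, 16.0, 16.0), voxel_mm=(2.0, 2.0, 2.0),
            n_gradients=21)


@pytest.fixture(scope="session")
def tiny_spec() -> u.PhantomSpec:
    return u.PhantomSpec(**TINY, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec) -> u.PhantomDataset:
    return u.build_phantom(tiny_spec)


@pytest.fixture(scope="session")
def uniform_phantom() -> u.PhantomDataset:
    """Edema-free phantom: constant cylindrical tensor everywhere."""
    return u.build_phantom(u.PhantomSpec(
        dims_mm=(80.0, 24.0, 24.0), voxel_mm=(2.0, 2.0, 2.0),
        n_gradients=21, omega_max=0.0, rng_seed=3))


@pytest.fixture(scope="session")
def directions21() -> np.ndarray:
    return u.hemisphere_directions(21)


@pytest.fixture()
def fast_ukf() -> u.UKFConfig:
    """Coarse-step tracking settings for unit tests on tiny grids."""
    return u.UKFConfig(model="1T", step_mm=0.6, max_steps=200,
                       min_length_mm=5.0)
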