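import numpy as np
import pytest

from petseg.grids import BinaryMask3D, Volume3D
from petseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def quiet_spec():
    """Small noiseless, homogeneous phantom spec (deterministic geometry)."""
    return PhantomSpec(
        grid_shape=(32, 32, 24),
        voxel_spacing=(4.0, 4.0, 2.0),
        body_semiaxes=(56.0, 52.0, 22.0),
        bladder_center=(34.0, 62.0, 23.0),
        bladder_radius=14.0,
        bladder_uptake=12.0,
        tumor_center=(84.0, 62.0, 23.0),
        tumor_semiaxes=(12.0, 10.0, 9.0),
        tumor_uptake=6.0,
        tumor_heterogeneity=0.0,
        noise_sd=0.0,
        pv_fwhm_mm=None,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_spec(quiet_spec):
    import dataclasses

    return dataclasses.replace(
        quiet_spec, noise_sd=0.1, tumor_heterogeneity=0.2, pv_fwhm_mm=4.5, seed=12
    )


@pytest.fixture(scope="session")
def quiet_case(quiet_spec):
    return generate_phantom(quiet_spec)


@pytest.fixture(scope="session")
def noisy_case(noisy_spec):
    return generate_phantom(noisy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    vals = rng.random((10, 12, 8)) + 0.5
    return Volume3D(vals, (4.0, 4.0, 2.0))


@pytest.fixture
def cube_mask():
    arr = np.zeros((10, 10, 10), dtype=np.uint8)
    arr[2:6, 3:7, 4:8] = 1
    return BinaryMask3D(arr, (4.0, 4.0, 2.0))
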