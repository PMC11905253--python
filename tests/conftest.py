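import numpy as np
import pytest

import edgemtf as em


@pytest.fixture(scope="session")
def small_cylinder_spec():
    """Desk-scale clean cylinder used by several suites (f50 = 0.3)."""
    return em.clean_cylinder(
        sigma_mm=em.sigma_for_f50(0.3), seed=7, dims=(128, 128, 26), radius_mm=40.0
    )


@pytest.fixture(scope="session")
def small_cylinder_volume(small_cylinder_spec):
    return em.generate_phantom(small_cylinder_spec)


@pytest.fixture(scope="session")
def cylinder_mask(small_cylinder_volume):
    vol = em.crop_longitudinal(small_cylinder_volume, 10.0)
    return vol, em.otsu_mask(vol)


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder_mask):
    _, mask = cylinder_mask
    return em.extract_surface(mask)


@pytest.fixture()
def integer_volume():
    """Small integer-valued HU volume for DICOM round-trip checks."""
    rng = np.random.default_rng(3)
    vox = rng.integers(-1000, 1000, size=(12, 10, 6)).astype(np.float32)
    return em.CTVolume(voxels=vox, spacing=(0.977, 0.977, 3.0), origin=np.array([-5.0, -4.0, 0.0]))
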