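import numpy as np
import pytest

import icv_sparse as icv

# analytic ellipsoid used across suites: semi-axes a (sagittal), b, c in mm
ELL_A, ELL_B, ELL_C = 60.0, 70.0, 80.0


@pytest.fixture(scope="session")
def ellipsoid_mask() -> icv.VoxelMask:
    """Voxelized ellipsoid with semi-axes (60, 70, 80) mm at 1 mm."""
    x, y, z = np.ogrid[-62:63, -72:73, -82:83]
    inside = (x / ELL_A) ** 2 + (y / ELL_B) ** 2 + (z / ELL_C) ** 2 <= 1.0
    return icv.VoxelMask(inside, voxel_size=1.0, subject_id="ellipsoid")


@pytest.fixture(scope="session")
def ellipsoid_profile() -> icv.AreaProfile:
    """Exact analytic sagittal area profile of the same ellipsoid.

    A(x) = pi * b * c * (1 - x^2/a^2), sampled at 1 mm, with one zero
    slice beyond each pole.
    """
    x = np.arange(-61, 62, dtype=float)
    areas = np.maximum(np.pi * ELL_B * ELL_C * (1 - (x / ELL_A) ** 2), 0.0)
    return icv.AreaProfile(
        orientation="sagittal",
        positions=x - x[0],
        areas=areas,
        subject_id="ellipsoid-analytic",
    )


@pytest.fixture(scope="session")
def small_cohort() -> list:
    """8-subject phantom cohort for fast evaluation tests."""
    return icv.generate_cohort(
        icv.PopulationSpec(n_female=5, n_male=3, seed=11)
    )


@pytest.fixture(scope="session")
def default_cohort() -> list:
    """The default 62-subject phantom cohort (39 female / 23 male)."""
    return icv.generate_cohort(icv.PopulationSpec(seed=42))
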