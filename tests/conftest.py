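import numpy as np
import pytest

from melrisk.imaging_io import LesionMask, Volume


@pytest.fixture()
def sphere_phantom():
    """Uniform SUL-4 sphere of radius 10 mm on a 1 mm isotropic grid."""
    shape = (40, 40, 40)
    spacing = (1.0, 1.0, 1.0)
    center = np.array([20, 20, 20])
    idx = np.indices(shape)
    r2 = sum((idx[d] - center[d]) ** 2 * spacing[d] ** 2 for d in range(3))
    inside = r2 <= 10.0**2
    pet = np.where(inside, 4.0, 0.0).astype(np.float32)
    vol = Volume(pet, spacing, "PET_MR")
    mask = LesionMask(inside, spacing, "sphere", "soft tissue")
    return vol, mask


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny rendered phantom cohort shared by feature-level tests."""
    from melrisk.synthetic_cohort import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_patients=4,
        shape=(48, 48, 56),
        spacing=(2.0, 2.0, 3.0),
        lesion_count_poisson_mean=2.0,
        seed=42,
    )
    return simulate_cohort(cfg)
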