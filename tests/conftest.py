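import numpy as np
import pytest

from adaptseg.phantom import desk_profile, generate_cohort


@pytest.fixture(scope="session")
def rigid_cohort():
    """Six purely rigid 56^3 phantom pairs (no deformation, no shrinkage):
    mid-treatment differs from pre-treatment only by the sampled rigid
    transform and independent noise, with ground truth in the manifest."""
    cfg = desk_profile(
        n_patients=6, grid=56, spacing=2.0, seed=202,
        deform_amplitude_mm=0.0, shrink_range=(1.0, 1.0),
        translation_mm=8.0, rotation_deg=4.0, missing_label_prob=0.0,
    )
    cfg.structures[0].radius_jitter = 0.05  # keep the thin bone above the
    # nearest-neighbour voxelization DSC ceiling at 2 mm
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def desk_cohort():
    """Default desk-scale cohort (deformation, shrinkage, missing labels)."""
    cfg = desk_profile(n_patients=6, seed=77)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, shape=(32, 32, 32), r_range=(3.0, 9.0)):
    """A random ellipsoidal mask, guaranteed non-empty."""
    shape = np.asarray(shape)
    while True:
        center = rng.uniform(0.25, 0.75, 3) * shape
        radii = rng.uniform(*r_range, 3)
        idx = np.indices(tuple(shape)).reshape(3, -1)
        d = (idx - center[:, None]) / radii[:, None]
        m = ((d * d).sum(axis=0) <= 1.0).reshape(tuple(shape))
        if m.any():
            return m
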