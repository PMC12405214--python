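import numpy as np
import pytest

from radfusion.phantom import PhantomParams, RoiSample, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 patients/class, 32 ROI samples, default class contrast."""
    return generate_cohort(PhantomParams(n_patients_per_class=4, seed=7))


@pytest.fixture(scope="session")
def one_sample(small_cohort):
    return small_cohort[0]


def make_roi(image, mask, label="control", region="ventricle", hemi="left"):
    return RoiSample("P000", label, region, hemi,
                     np.asarray(image, dtype=float), np.asarray(mask, bool))


@pytest.fixture
def square_roi():
    """A 128x128 slice with a solid square mask centered at (64, 64)."""
    img = np.zeros((128, 128))
    mask = np.zeros((128, 128), bool)
    mask[60:69, 60:69] = True
    img[mask] = 0.8
    return make_roi(img, mask)
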