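import numpy as np
import pytest

import tractload as tl
from tractload.synthetic import CohortParams, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    """Default two-hemisphere synthetic tract template (64x64x40, 2 mm)."""
    return tl.make_tract_template(tl.default_tract_specs())


@pytest.fixture(scope="session")
def demo_cohort(atlas):
    """27-subject cohort with lesions, generated at the default parameters."""
    cohort, lesions, truth = simulate_cohort(CohortParams(seed=11), atlas)
    return cohort, lesions, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mask(rng, shape, density=0.2, affine=None):
    """Random binary mask helper shared across tests."""
    if affine is None:
        affine = np.eye(4)
    data = (rng.random(shape) < density).astype(np.uint8)
    return tl.MaskVolume(data=data, affine=affine)
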