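import numpy as np
import pytest
from hypothesis import settings

from perirec import PhantomSpec, generate_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


#: compact geometry that fits a 48-voxel grid; used where full 64-voxel
#: phantoms would be needlessly slow
SMALL_PHANTOM = dict(
    grid_shape=(48, 48, 48), cavity_radius_mm=6.0, shell_thickness_mm=8.0,
    recurrence_depth_mm=6.0, brain_margin_mm=4.0,
)


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(PhantomSpec(seed=7, **SMALL_PHANTOM))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
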