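import numpy as np
import pytest
from scipy.spatial.transform import Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


def random_rigid_motion(rng, translation_scale=3.0):
    """A random proper rotation and translation."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=translation_scale, size=3)
    return R, t


@pytest.fixture
def ideal_helix_31():
    from helixgeom import build_ideal_helix

    return build_ideal_helix(n_atoms=31)
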