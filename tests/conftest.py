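import numpy as np
import pytest

import hopcrystal as hc
from hopcrystal import synthetic_data as sd


@pytest.fixture(scope="session")
def benzene():
    return sd.make_acene_template(1)


@pytest.fixture(scope="session")
def anthracene():
    return sd.make_acene_template(3)


@pytest.fixture(scope="session")
def stack_structure(anthracene):
    """Cofacial anthracene π-stack, spacing 3.5 Å, molecules identified."""
    struct = sd.make_stack_crystal(sd.StackSpec(template=anthracene, spacing=3.5))
    return hc.identify_molecules(struct)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    rot = q * np.sign(np.diag(r))
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return rot, rng.uniform(-20, 20, size=3)
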