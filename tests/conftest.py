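import numpy as np
import pytest

from gagflex.ensemble import sample_ensemble, two_state_spec
from gagflex.topology import build_extended_chain, build_topology


@pytest.fixture(scope="session")
def ha_top():
    return build_topology("HA", 5)


@pytest.fixture(scope="session")
def ha_extended(ha_top):
    return build_extended_chain(ha_top)


@pytest.fixture(scope="session")
def two_state_traj(ha_top):
    """Small two-regime ensemble shared by feature/cluster/FES tests."""
    return sample_ensemble(two_state_spec(ha_top, n_frames=200, seed=42))


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=2.0, size=3)
    return Q, t
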