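import numpy as np
import pytest

from tpmflex import (CoiledCoilParams, WLCParams, gen_coiled_coil,
                     gen_wlc_ensemble)
from tpmflex.skeleton import SkeletonFrame


@pytest.fixture(scope="session")
def straight_helix_frame():
    """Two straight ideal alpha-helices with axes on z (degenerate radius)."""
    return gen_coiled_coil(CoiledCoilParams(n_residues=40, superhelix_radius=0.0))


@pytest.fixture(scope="session")
def coiled_coil_frame():
    """Default supercoiled two-chain fixture, 60 residues per chain."""
    return gen_coiled_coil(CoiledCoilParams(n_residues=60))


@pytest.fixture(scope="session")
def wlc_skeletons():
    """3000-chain WLC ensemble at L_p = 161 nm as skeleton frames."""
    nodes = gen_wlc_ensemble(WLCParams(n_chains=3000, n_segments=30,
                                       segment_length=1.4,
                                       persistence_length=161.0, seed=11))
    return [SkeletonFrame.from_nodes(n) for n in nodes]


@pytest.fixture
def random_rigid_motion():
    """A fixed, reproducible random rotation matrix and translation."""
    rng = np.random.default_rng(42)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return Q, t
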