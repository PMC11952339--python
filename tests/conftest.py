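import numpy as np
import pytest

from enseval.core import Ensemble
from enseval.synthetic import build_ideal_chain, torsion_jitter_ensemble

HELIX_SEQ = "AKLSEVFAKLSEVF"
MIXED_SEQ = "AKLSEVFGAKLSEVF"


@pytest.fixture(scope="session")
def helix_ensemble():
    """Single-frame ideal alpha-helix (phi=-57, psi=-47), clash-free."""
    return build_ideal_chain(HELIX_SEQ, "helix")


@pytest.fixture(scope="session")
def extended_ensemble():
    """Single-frame fully extended chain (phi=psi=180)."""
    return build_ideal_chain(MIXED_SEQ, "extended")


@pytest.fixture(scope="session")
def jittered_helix(helix_ensemble):
    """10-frame helix with 5-degree torsion jitter, fixed seed."""
    return torsion_jitter_ensemble(
        helix_ensemble.topology, helix_ensemble.frames[0], 10, 5.0, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-20, 20, 3)
    return R.as_matrix(), t


def transformed_ensemble(ensemble, R, t):
    from enseval.core import Conformation

    return Ensemble(
        topology=ensemble.topology,
        frames=[Conformation(f.coords @ R.T + t) for f in ensemble.frames],
        temperature=ensemble.temperature,
        label=ensemble.label,
    )
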