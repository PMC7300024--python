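import numpy as np
import pytest

from tmrepack import synthetic_data as syn
from tmrepack.cavity_volume import helix_selection_map


@pytest.fixture(scope="session")
def ideal_bundle():
    """Noiseless 12-helix bundle (radius 15 Å, 20 residues/helix) + selections."""
    traj, config = syn.make_bundle(syn.BundleSpec())
    return traj, config


@pytest.fixture(scope="session")
def ideal_bundle_helices(ideal_bundle):
    traj, config = ideal_bundle
    return helix_selection_map(traj, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
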