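import numpy as np
import pytest

from mdscape.structure_model import DomainMap, Structure, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ca_chain():
    """Ten-residue CA-only chain along x, 3.8 A spacing."""
    n = 10
    coords = np.zeros((n, 3))
    coords[:, 0] = 3.8 * np.arange(n)
    return Structure(
        residue_indices=np.arange(1, n + 1),
        residue_names=["ALA"] * n,
        atom_names=["CA"] * n,
        coords=coords,
        identifier="ca-chain",
    )


@pytest.fixture
def full_length_chain():
    """CA-only chain spanning residues 1..1275 (the real protein's length)."""
    n = 1275
    coords = np.zeros((n, 3))
    coords[:, 0] = 3.8 * np.arange(n)
    return Structure(np.arange(1, n + 1), ["GLY"] * n, ["CA"] * n, coords)


@pytest.fixture
def two_domain_spec():
    """Two compact 10-atom domains 30 A apart, as an EnsembleSpec-ready pair."""
    from mdscape.synthetic_data import build_toy_topology

    return build_toy_topology(
        {"A": 10, "B": 10}, centers={"A": (0, 0, 0), "B": (30, 0, 0)}
    )


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.uniform(-20, 20, size=3)
    return rotation, translation


@pytest.fixture
def blob_scores(rng):
    """Two spherical Gaussian clusters separated by 20 sigma, with labels."""
    n = 200
    a = rng.normal(0.0, 1.0, size=(n, 2))
    b = rng.normal(0.0, 1.0, size=(n, 2)) + np.array([20.0, 0.0])
    x = np.vstack([a, b])
    labels = np.repeat([0, 1], n)
    return x, labels
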