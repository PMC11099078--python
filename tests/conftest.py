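import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mig.model_io import AtomRecord, RigidTransform, StructureModel


def random_rigid_transform(rng: np.random.Generator, scale: float = 50.0) -> RigidTransform:
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.normal(0.0, scale, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_chain_model():
    """Minimal 2-chain, 10-atom model."""
    atoms = []
    for i in range(6):
        atoms.append(AtomRecord("C", "CA", "ALA", i + 1, "A",
                                np.array([float(i), 0.0, 0.0]), 12.011))
    for i in range(4):
        atoms.append(AtomRecord("N", "N", "GLY", i + 1, "B",
                                np.array([0.0, float(i), 1.0]), 14.007))
    return StructureModel(atoms)


@pytest.fixture
def random_atoms(rng):
    """50 atoms with random positions and masses."""
    return [
        AtomRecord("C", "CA", "ALA", i + 1, "A",
                   rng.normal(0.0, 20.0, 3), float(rng.uniform(1.0, 30.0)))
        for i in range(50)
    ]
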