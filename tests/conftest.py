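import numpy as np
import pytest

from symstack.fixtures import (
    FibrilSpec,
    LigandSpec,
    fibril_operator,
    make_helical_fibril,
    make_planar_ligand,
)
from symstack.geometry import AffineOperator, ScrewParameters, screw_to_operator
from symstack.scoring import VdwParameterTable
from symstack.stacking import LigandAtom, LigandPose


@pytest.fixture
def z_axis():
    return np.array([0.0, 0.0, 1.0])


@pytest.fixture
def tau_like_spec():
    return FibrilSpec(n_monomers=5, rise=4.7, twist_deg=-1.0, seed=1)


@pytest.fixture
def tau_like_fibril(tau_like_spec):
    return make_helical_fibril(tau_like_spec)


@pytest.fixture
def tau_like_operator(tau_like_spec):
    return fibril_operator(tau_like_spec)


@pytest.fixture
def hexagon():
    """Flat 6-ring in the z=0 plane, 1.39 Å bonds, centered at the origin."""
    return make_planar_ligand(LigandSpec(ring_size=6))


@pytest.fixture
def round_table():
    """Round-number LJ table so analytic expectations are exact."""
    return VdwParameterTable(
        params={"X": (1.0, 1.7), "Y": (0.25, 2.0)},
        element_defaults={"C": "X", "N": "Y", "O": "Y", "H": "X"},
    )


@pytest.fixture
def translation_op():
    """Pure translation by the canonical 4.7 Å rise."""
    return AffineOperator(np.eye(3), np.array([0.0, 0.0, 4.7]))


def random_operator(rng: np.random.Generator) -> AffineOperator:
    """Uniform random proper rotation + bounded random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-8.0, 8.0, size=3)
    return AffineOperator(R, t)


def random_pose(rng: np.random.Generator, n_atoms: int = 10) -> LigandPose:
    coords = rng.uniform(-4.0, 4.0, size=(n_atoms, 3))
    atoms = [LigandAtom("C", f"C{i+1}", c) for i, c in enumerate(coords)]
    return LigandPose("rand", atoms)


def make_screw(axis, twist_deg, rise, axis_point=(0.0, 0.0, 0.0)) -> AffineOperator:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return screw_to_operator(
        ScrewParameters(axis=axis, twist_deg=twist_deg, rise=rise,
                        axis_point=np.asarray(axis_point, dtype=float))
    )
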