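"""Deterministic synthetic fixtures: helical fibrils, planar ligands, screens.

Everything here is generated from a seed so tests and demos run without any
downloaded structure.  The fibril generator builds a template monomer (an
idealized beta-strand trace) and replicates it with an exact screw operator,
which makes operator-derivation round trips checkable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Atom,
    AffineOperator,
    Chain,
    FibrilStructure,
    ScrewParameters,
    screw_to_operator,
)
from .metrics import ScreenRecord
from .stacking import LigandAtom, LigandPose

__all__ = [
    "FibrilSpec",
    "LigandSpec",
    "ScreenSpec",
    "FixtureSpec",
    "make_helical_fibril",
    "fibril_operator",
    "make_planar_ligand",
    "make_screen_set",
]

_RESIDUE_CYCLE = ("ALA", "GLY", "SER", "VAL", "LEU", "THR")
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

# beta-strand-like CA trace: 3.8 Å consecutive spacing from an in-plane
# advance plus an alternating out-of-plane pleat
_CA_SPACING = 3.8
_PLEAT = 1.15


@dataclass(frozen=True)
class FibrilSpec:
    n_monomers: int = 5
    rise: float = 4.7
    twist_deg: float = -1.0
    residues_per_monomer: int = 24
    radial_offset: float = 10.0
    jitter_sigma: float = 0.0
    backbone: bool = False
    n_protofilaments: int = 1
    seed: int = 0


@dataclass(frozen=True)
class LigandSpec:
    ring_size: int = 6
    bond_length: float = 1.39
    planar: bool = True
    n_substituents: int = 0
    element_palette: tuple[str, ...] = ("C",)
    seed: int = 0


@dataclass(frozen=True)
class ScreenSpec:
    n_actives: int = 16
    n_decoys: int = 800
    active_mu: float = -40.0
    active_sigma: float = 5.0
    decoy_mu: float = -25.0
    decoy_sigma: float = 5.0
    seed: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    fibril: FibrilSpec = field(default_factory=FibrilSpec)
    ligand: LigandSpec = field(default_factory=LigandSpec)
    screen: ScreenSpec = field(default_factory=ScreenSpec)


def fibril_operator(spec: FibrilSpec) -> AffineOperator:
    """The exact screw operator (about the z axis) used by the generator."""
    return screw_to_operator(
        ScrewParameters(
            axis=np.array([0.0, 0.0, 1.0]),
            twist_deg=spec.twist_deg,
            rise=spec.rise,
            axis_point=np.zeros(3),
        )
    )


# per-residue in-plane turn of the CA trace; a long monomer wraps into a
# C-shape in the layer plane, which keeps the small-twist rotation axis
# well conditioned during operator derivation
_TURN_PER_RESIDUE_DEG = 5.0


def _template_monomer(spec: FibrilSpec, chain_id: str, y_shift: float = 0.0) -> Chain:
    dx = np.sqrt(_CA_SPACING**2 - (2.0 * _PLEAT) ** 2)
    ca_positions = []
    point = np.zeros(3)
    for i in range(spec.residues_per_monomer):
        ca_positions.append(
            point + np.array([0.0, 0.0, _PLEAT * (1 if i % 2 == 0 else -1)])
        )
        phi = np.deg2rad(_TURN_PER_RESIDUE_DEG) * i
        point = point + dx * np.array([np.cos(phi), np.sin(phi), 0.0])
    ca_positions = np.array(ca_positions)
    ca_positions[:, :2] -= ca_positions[:, :2].mean(axis=0)
    ca_positions[:, 0] += spec.radial_offset
    ca_positions[:, 1] += y_shift

    atoms: list[Atom] = []
    for i, ca in enumerate(ca_positions):
        res_name = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        res_id = i + 1
        if spec.backbone:
            atoms.append(Atom("N", "N", res_id, res_name, ca + [-1.2, 0.6, 0.3]))
        atoms.append(Atom("CA", "C", res_id, res_name, ca))
        if spec.backbone:
            atoms.append(Atom("C", "C", res_id, res_name, ca + [1.1, 0.7, -0.3]))
            atoms.append(Atom("O", "O", res_id, res_name, ca + [1.3, 1.9, -0.3]))
    return Chain(chain_id, atoms)


def make_helical_fibril(spec: FibrilSpec = FibrilSpec()) -> FibrilStructure:
    """Build a screw-symmetric fibril: monomer k is op^k of the template.

    With ``jitter_sigma > 0``, isotropic Gaussian noise is added to every
    atom after replication (for derivation-robustness tests).
    """
    rng = np.random.default_rng(spec.seed)
    op = fibril_operator(spec)
    chains: list[Chain] = []
    protofilaments: dict[str, list[str]] = {}
    cid_iter = iter(_CHAIN_IDS)
    for p in range(spec.n_protofilaments):
        template = _template_monomer(spec, "tmpl", y_shift=80.0 * p)
        labels = []
        for k in range(spec.n_monomers):
            cid = next(cid_iter)
            coords = op.power(k).apply(template.coords())
            if spec.jitter_sigma > 0:
                coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)
            atoms = [
                Atom(a.name, a.element, a.res_id, a.res_name, c)
                for a, c in zip(template.atoms, coords)
            ]
            chains.append(Chain(cid, atoms))
            labels.append(cid)
        protofilaments[f"P{p + 1}"] = labels
    fibril = FibrilStructure(chains=chains, protofilaments=protofilaments)
    fibril.validate()
    return fibril


def make_planar_ligand(spec: LigandSpec = LigandSpec(), mol_id: str = "LIG") -> LigandPose:
    """Regular-polygon ring in the z = 0 plane, aromatic-like bond lengths.

    The non-planar variant lifts one ring corner well out of the plane
    (an sp3-corner mimic used to exercise clash rejection of 3D stackers).
    Substituents extend radially in-plane with elements drawn from the
    palette, deterministically per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.ring_size
    radius = spec.bond_length / (2.0 * np.sin(np.pi / n))
    atoms: list[LigandAtom] = []
    bonds: list[tuple[int, int, int]] = []
    for i in range(n):
        theta = 2.0 * np.pi * i / n
        coord = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        atoms.append(LigandAtom("C", f"C{i + 1}", coord))
        bonds.append((i, (i + 1) % n, 1))
    if not spec.planar:
        atoms[0].coord = atoms[0].coord + np.array([0.0, 0.0, 1.5])
    for s in range(spec.n_substituents):
        parent = s % n
        elem = str(rng.choice(list(spec.element_palette)))
        direction = atoms[parent].coord.copy()
        direction[2] = 0.0
        direction /= max(np.linalg.norm(direction), 1e-9)
        coord = atoms[parent].coord + spec.bond_length * direction
        atoms.append(LigandAtom(elem, f"{elem}{n + s + 1}", coord))
        bonds.append((parent, len(atoms) - 1, 1))
    return LigandPose(mol_id, atoms, bonds)


def make_screen_set(spec: ScreenSpec = ScreenSpec()) -> list[ScreenRecord]:
    """Seeded normal score distributions for actives and decoys."""
    rng = np.random.default_rng(spec.seed)
    records = [
        ScreenRecord(
            f"active_{i + 1}",
            float(rng.normal(spec.active_mu, spec.active_sigma)),
            "active",
        )
        for i in range(spec.n_actives)
    ]
    records += [
        ScreenRecord(
            f"decoy_{i + 1}",
            float(rng.normal(spec.decoy_mu, spec.decoy_sigma)),
            "decoy",
        )
        for i in range(spec.n_decoys)
    ]
    return records
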