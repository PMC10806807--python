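"""Ligand–ligand van der Waals stacking energy and pose ranking.

Energy model: 12-6 Lennard-Jones, ``E(r) = eps_ij * ((rmin_ij/r)**12 -
2*(rmin_ij/r)**6)``, summed over all inter-pose atom pairs, with
Lorentz–Berthelot combination (arithmetic ``rmin = rmin_half_i +
rmin_half_j``, geometric ``eps = sqrt(eps_i * eps_j)``).  The stacking
score adds this term for the nearest symmetry image of a pose that has
already passed the self-clash filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SingularGeometryError, SymstackError
from .geometry import AffineOperator
from .stacking import ClashConfig, LigandPose, symmetry_clash_check

__all__ = [
    "VdwParameterTable",
    "StackEnergyReport",
    "assign_vdw_types",
    "pair_vdw_energy",
    "stack_score",
    "rank_poses",
    "load_default_table",
]


@dataclass
class VdwParameterTable:
    """vdW parameters keyed by type label, with per-element default types."""

    params: dict[str, tuple[float, float]]
    element_defaults: dict[str, str] = field(default_factory=dict)
    combination_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        for label, (eps, rmin_half) in self.params.items():
            if eps < 0:
                raise ParameterError(f"type {label!r}: epsilon must be >= 0")
            if rmin_half <= 0:
                raise ParameterError(f"type {label!r}: rmin_half must be > 0")
        for elem, label in self.element_defaults.items():
            if label not in self.params:
                raise ParameterError(
                    f"default type {label!r} for element {elem!r} is not in the table"
                )

    def lookup(self, vdw_type: str) -> tuple[float, float]:
        try:
            return self.params[vdw_type]
        except KeyError:
            raise ParameterError(f"vdW type {vdw_type!r} not in parameter table")

    def default_type(self, element: str) -> str:
        key = element.strip().capitalize()
        if key not in self.element_defaults:
            raise ParameterError(f"no default vdW type for element {element!r}")
        return self.element_defaults[key]

    def pair_params(self, type_i: str, type_j: str) -> tuple[float, float]:
        eps_i, rh_i = self.lookup(type_i)
        eps_j, rh_j = self.lookup(type_j)
        return float(np.sqrt(eps_i * eps_j)), rh_i + rh_j

    @classmethod
    def from_text(cls, text: str) -> "VdwParameterTable":
        """Parse the whitespace-delimited table format.

        Lines: ``type epsilon rmin_half`` for parameters and
        ``default element type`` for element fallbacks; ``#`` comments.
        """
        params: dict[str, tuple[float, float]] = {}
        defaults: dict[str, str] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if fields[0].lower() == "default":
                if len(fields) != 3:
                    raise ParameterError(f"line {lineno}: expected 'default ELEMENT TYPE'")
                defaults[fields[1].capitalize()] = fields[2]
            else:
                if len(fields) != 3:
                    raise ParameterError(
                        f"line {lineno}: expected 'TYPE EPSILON RMIN_HALF'"
                    )
                try:
                    params[fields[0]] = (float(fields[1]), float(fields[2]))
                except ValueError as exc:
                    raise ParameterError(f"line {lineno}: {exc}") from exc
        if not params:
            raise ParameterError("parameter table contains no types")
        return cls(params=params, element_defaults=defaults)

    @classmethod
    def from_file(cls, path) -> "VdwParameterTable":
        with open(path) as fh:
            return cls.from_text(fh.read())


def load_default_table() -> VdwParameterTable:
    """Load the united-atom parameter table shipped with the package."""
    text = resources.files("symstack.data").joinpath("vdw_params.txt").read_text()
    return VdwParameterTable.from_text(text)


def assign_vdw_types(pose: LigandPose, table: VdwParameterTable) -> LigandPose:
    """Return a copy of the pose where every atom carries a resolvable type.

    Explicit per-atom types from the input file are preserved; untyped atoms
    fall back to the table's element default.  Atoms that cannot be typed
    are reported together in one error.
    """
    new_atoms = []
    unparameterized = []
    for i, atom in enumerate(pose.atoms):
        vdw_type = atom.vdw_type
        if vdw_type is not None and vdw_type in table.params:
            new_atoms.append(atom)
            continue
        try:
            resolved = table.default_type(atom.element)
        except ParameterError:
            unparameterized.append(f"atom {i} ({atom.name}, element {atom.element})")
            continue
        new_atoms.append(replace(atom, vdw_type=resolved))
    if unparameterized:
        raise ParameterError(
            f"pose {pose.mol_id!r}: no vdW parameters for: "
            + "; ".join(unparameterized)
        )
    return LigandPose(pose.mol_id, new_atoms, list(pose.bonds))


def pair_vdw_energy(
    pose_a: LigandPose, pose_b: LigandPose, table: VdwParameterTable
) -> float:
    """Total 12-6 LJ interaction energy (kcal/mol) between two typed poses."""
    types_a = [a.vdw_type for a in pose_a.atoms]
    types_b = [b.vdw_type for b in pose_b.atoms]
    if any(t is None for t in types_a) or any(t is None for t in types_b):
        raise ParameterError("both poses must be fully typed (run assign_vdw_types)")

    eps_a = np.array([table.lookup(t)[0] for t in types_a])
    rh_a = np.array([table.lookup(t)[1] for t in types_a])
    eps_b = np.array([table.lookup(t)[0] for t in types_b])
    rh_b = np.array([table.lookup(t)[1] for t in types_b])

    r = cdist(pose_a.coords(), pose_b.coords())
    if np.any(r < 1e-12):
        raise SingularGeometryError(
            f"zero interatomic distance between {pose_a.mol_id!r} and {pose_b.mol_id!r}"
        )
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    rmin_ij = rh_a[:, None] + rh_b[None, :]
    x6 = (rmin_ij / r) ** 6
    return float(np.sum(eps_ij * (x6 * x6 - 2.0 * x6)))


@dataclass
class StackEnergyReport:
    """Outcome of filtering + scoring one pose against its symmetry stack."""

    pose_id: str
    passes_clash: bool
    min_image_distance: float
    ligand_ligand_vdw: Optional[float] = None
    total_score: Optional[float] = None
    backend: str = "builtin-lj"

    def __post_init__(self) -> None:
        if not self.passes_clash and self.ligand_ligand_vdw is not None:
            raise SymstackError("clashing poses must not carry an energy")


def stack_score(
    pose: LigandPose,
    op: AffineOperator,
    table: VdwParameterTable,
    cfg: ClashConfig = ClashConfig(),
    protein_terms: Optional[dict[str, float]] = None,
    n_images: int = 1,
) -> StackEnergyReport:
    """Clash-filter a pose; if it passes, add the ligand–ligand vdW energy.

    ``n_images`` > 1 sums image pairs up to the k-th image (sensitivity
    analysis); the default scores only the nearest pair.
    """
    passes, min_dist = symmetry_clash_check(pose, op, cfg)
    if not passes:
        return StackEnergyReport(pose.mol_id, False, min_dist)
    typed = assign_vdw_types(pose, table)
    energy = 0.0
    for k in range(1, n_images + 1):
        energy += pair_vdw_energy(typed, typed.transformed(op.power(k)), table)
    total = None
    if protein_terms is not None:
        total = float(sum(protein_terms.values())) + energy
    return StackEnergyReport(
        pose.mol_id, True, min_dist, ligand_ligand_vdw=energy, total_score=total
    )


def rank_poses(reports: list[StackEnergyReport]) -> list[StackEnergyReport]:
    """Ascending sort of passing poses by total (else vdW) score.

    Clash-failed reports are excluded.  Mixing reports where some carry a
    total score and some only a vdW term is an error.
    """
    passing = [r for r in reports if r.passes_clash]
    has_total = {r.total_score is not None for r in passing}
    if len(has_total) > 1:
        raise SymstackError("cannot rank reports with mixed score term sets")
    use_total = has_total == {True}

    def key(r: StackEnergyReport):
        score = r.total_score if use_total else r.ligand_ligand_vdw
        return (score, r.pose_id)

    return sorted(passing, key=key)
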