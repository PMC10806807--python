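"""Rigid-body Metropolis Monte Carlo refinement of ligand stacks.

The refined object is a single monomer pose; the symmetry mates are
regenerated from it at every step, so the whole stack moves coherently and
the screw symmetry is exact throughout.  The objective is a per-monomer
stack energy estimated from the three-pose stack (the pose plus its two
nearest symmetry mates) under a pluggable backend: the builtin
Lennard-Jones sum, or any external command that evaluates a geometry.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np

from .errors import BackendError, PoseError
from .geometry import AffineOperator
from .scoring import VdwParameterTable, assign_vdw_types, pair_vdw_energy
from .stacking import ClashConfig, LigandPose, build_stack, pose_rmsd, symmetry_clash_check

__all__ = [
    "EnergyBackend",
    "BuiltinLJBackend",
    "CommandBackend",
    "MCConfig",
    "MCResult",
    "per_monomer_energy",
    "propose_move",
    "run_mc",
]

HARTREE_TO_KCAL = 627.509474


class EnergyBackend(Protocol):
    """Anything that can score a geometry (a list of poses) in kcal/mol."""

    label: str

    def total_energy(self, poses: Sequence[LigandPose]) -> float: ...


class BuiltinLJBackend:
    """Inter-molecular Lennard-Jones sum over all pose pairs.

    Intramolecular energy is constant under rigid motion and is defined as
    zero, so a single pose scores 0 and the per-monomer formula reduces to
    pure interface energies.
    """

    label = "builtin-lj"

    def __init__(self, table: VdwParameterTable):
        self.table = table

    def total_energy(self, poses: Sequence[LigandPose]) -> float:
        typed = [assign_vdw_types(p, self.table) for p in poses]
        total = 0.0
        for i in range(len(typed)):
            for j in range(i + 1, len(typed)):
                total += pair_vdw_energy(typed[i], typed[j], self.table)
        return total


class CommandBackend:
    """External energy program invoked per geometry.

    The geometry (all poses concatenated) is written as an XYZ file to a
    temporary path; the command template is run with ``{xyz}`` substituted
    (or the path appended if no placeholder is present); the first token of
    standard output must parse as the energy.  ``units`` is ``"kcal"`` or
    ``"hartree"``.
    """

    def __init__(self, command_template: str, units: str = "kcal"):
        if units not in ("kcal", "hartree"):
            raise BackendError(f"unknown energy unit {units!r}")
        self.command_template = command_template
        self.units = units
        self.label = f"cmd:{command_template}"

    @staticmethod
    def _write_xyz(poses: Sequence[LigandPose], path: Path) -> None:
        lines = []
        atoms = [(a.element, a.coord) for p in poses for a in p.atoms]
        lines.append(str(len(atoms)))
        lines.append("symstack geometry")
        for elem, xyz in atoms:
            lines.append(f"{elem:<2s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}")
        path.write_text("\n".join(lines) + "\n")

    def total_energy(self, poses: Sequence[LigandPose]) -> float:
        with tempfile.TemporaryDirectory(prefix="symstack_") as tmp:
            xyz = Path(tmp) / "geometry.xyz"
            self._write_xyz(poses, xyz)
            if "{xyz}" in self.command_template:
                cmd = self.command_template.replace("{xyz}", str(xyz))
            else:
                cmd = f"{self.command_template} {shlex.quote(str(xyz))}"
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise BackendError(
                    f"backend command failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip()[:500]}"
                )
            tokens = proc.stdout.split()
            if not tokens:
                raise BackendError("backend produced no output")
            try:
                value = float(tokens[0])
            except ValueError:
                raise BackendError(
                    f"backend reply is not a number: {proc.stdout.strip()[:200]!r}"
                )
        return value * HARTREE_TO_KCAL if self.units == "hartree" else value


def per_monomer_energy(
    pose: LigandPose, op: AffineOperator, backend: EnergyBackend
) -> float:
    """Per-monomer stack energy from the trimer estimate.

    ``[E(trimer) - 3 E(monomer)] / 2``: the central monomer owns half of
    each of its two interfaces, and the small mate–mate coupling inside the
    trimer is retained.  Converges to the infinite-stack per-monomer
    interaction energy for short-ranged backends.
    """
    stack = build_stack(pose, op, n_up=1, n_down=1)
    e_trimer = backend.total_energy(stack)
    e_monomer = backend.total_energy([pose])
    return (e_trimer - 3.0 * e_monomer) / 2.0


@dataclass(frozen=True)
class MCConfig:
    """Metropolis–Hastings settings.

    Translations are i.i.d. normal per component; rotations are isotropic
    on SO(3): axis uniform on the sphere, angle ``|N(0, rotation_sigma²)|``,
    applied about the pose's heavy-atom centroid.
    """

    n_steps: int = 1000
    translation_sigma: float = 0.2
    rotation_sigma: float = 2.0
    kT: float = 0.593
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise PoseError("n_steps must be >= 1")
        if self.translation_sigma < 0 or self.rotation_sigma < 0:
            raise PoseError("proposal sigmas must be >= 0")
        if self.kT <= 0:
            raise PoseError("kT must be > 0")


@dataclass
class MCResult:
    start_energy: float
    best_energy: float
    best_pose: LigandPose
    accepted_energy_trace: list[float]
    rmsd_to_start: float
    delta_energy: float
    acceptance_fraction: float
    best_pose_clashes: bool
    backend: str = "builtin-lj"
    n_steps: int = 0
    seed: int = 0


def propose_move(
    rng: np.random.Generator, cfg: MCConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one rigid move: (translation vector, rotation matrix).

    Consumes a fixed number of variates per call (3 translation normals,
    3 axis normals, 1 angle normal) so traces are reproducible.
    """
    translation = rng.normal(0.0, 1.0, size=3) * cfg.translation_sigma
    axis = rng.normal(0.0, 1.0, size=3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    angle = abs(rng.normal(0.0, 1.0)) * np.deg2rad(cfg.rotation_sigma)
    if angle < 1e-15:
        rotation = np.eye(3)
    else:
        from scipy.spatial.transform import Rotation

        rotation = Rotation.from_rotvec(axis * angle).as_matrix()
    return translation, rotation


def _moved_coords(
    coords: np.ndarray, center: np.ndarray, translation: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    return (coords - center) @ rotation.T + center + translation


def run_mc(
    pose: LigandPose,
    op: AffineOperator,
    cfg: MCConfig,
    backend: EnergyBackend,
    clash_cfg: Optional[ClashConfig] = None,
) -> MCResult:
    """Metropolis–Hastings minimization of the per-monomer stack energy.

    Rigid moves only; symmetry mates are rebuilt from the moved monomer at
    every evaluation.  Returns the minimum-energy configuration over all
    evaluated states (accepted or not).  Identical (pose, op, cfg, backend)
    reproduce the trace bit-exactly.
    """
    clash_cfg = clash_cfg or ClashConfig()
    rng = np.random.default_rng(cfg.seed)

    try:
        current_energy = per_monomer_energy(pose, op, backend)
    except BackendError as exc:
        raise BackendError(f"backend failed on the starting pose: {exc}") from exc

    start_energy = current_energy
    current = pose
    best_pose = pose
    best_energy = current_energy
    trace = [current_energy]
    n_accept = 0

    for step in range(cfg.n_steps):
        translation, rotation = propose_move(rng, cfg)
        center = current.centroid(heavy_only=True)
        candidate = current.with_coords(
            _moved_coords(current.coords(), center, translation, rotation)
        )
        try:
            cand_energy = per_monomer_energy(candidate, op, backend)
        except BackendError as exc:
            raise BackendError(f"backend failed at MC step {step}: {exc}") from exc

        if cand_energy < best_energy:
            best_energy = cand_energy
            best_pose = candidate

        delta = cand_energy - current_energy
        if delta <= 0 or rng.random() < np.exp(-delta / cfg.kT):
            current = candidate
            current_energy = cand_energy
            n_accept += 1
        trace.append(current_energy)

    passes, _ = symmetry_clash_check(best_pose, op, clash_cfg)
    return MCResult(
        start_energy=start_energy,
        best_energy=best_energy,
        best_pose=best_pose,
        accepted_energy_trace=trace,
        rmsd_to_start=pose_rmsd(best_pose, pose, heavy_only=True),
        delta_energy=best_energy - start_energy,
        acceptance_fraction=n_accept / cfg.n_steps,
        best_pose_clashes=not passes,
        backend=getattr(backend, "label", "unknown"),
        n_steps=cfg.n_steps,
        seed=cfg.seed,
    )
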