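"""Ligand symmetry stacks: image generation, clash filtering, geometry.

A pose that binds a screw-symmetric fibril is implicitly repeated at every
monomer. Generating the images with the fibril operator lets us reject
poses whose images collide with themselves and measure stack geometry
(inter-image minimum distance, interplanar separation, RMSD between poses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import PlaneFitError, PoseError
from .geometry import AffineOperator

__all__ = [
    "LigandAtom",
    "LigandPose",
    "ClashConfig",
    "symmetry_clash_check",
    "build_stack",
    "interplanar_distance",
    "pose_rmsd",
]

_HYDROGENS = {"H", "D", "T"}


@dataclass
class LigandAtom:
    element: str
    name: str
    coord: np.ndarray
    charge: Optional[float] = None
    vdw_type: Optional[str] = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)
        self.element = self.element.strip()

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGENS


@dataclass
class LigandPose:
    """An ordered, typed atom set in the fibril coordinate frame."""

    mol_id: str
    atoms: list[LigandAtom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(a.is_heavy for a in self.atoms):
            raise PoseError(f"pose {self.mol_id!r} has no heavy atoms")
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise PoseError(f"pose {self.mol_id!r} has non-finite coordinates")
        if len(self.atoms) > 1:
            # duplicate coordinates indicate a corrupt record
            tree = cKDTree(coords)
            pairs = tree.query_pairs(1e-9)
            if pairs:
                i, j = sorted(pairs)[0]
                raise PoseError(
                    f"pose {self.mol_id!r}: atoms {i} and {j} share coordinates"
                )

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coord for a in atoms], dtype=float).reshape(-1, 3)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def transformed(self, op: AffineOperator) -> "LigandPose":
        new_coords = op.apply(self.coords())
        new_atoms = [
            replace(a, coord=c) for a, c in zip(self.atoms, new_coords)
        ]
        return LigandPose(self.mol_id, new_atoms, list(self.bonds))

    def with_coords(self, coords: np.ndarray) -> "LigandPose":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] != len(self.atoms):
            raise PoseError("coordinate array does not match atom count")
        new_atoms = [replace(a, coord=c) for a, c in zip(self.atoms, coords)]
        return LigandPose(self.mol_id, new_atoms, list(self.bonds))

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        return self.coords(heavy_only=heavy_only).mean(axis=0)


@dataclass(frozen=True)
class ClashConfig:
    """Self-clash rule: reject a pose whose nearest image comes too close.

    ``cutoff`` defaults to 2.0 Å; ``atom_selection`` is ``"all"`` (use every
    atom, hydrogens included) or ``"heavy"``.  ``n_images`` extends the check
    to the ±k-th images for elongated ligands.
    """

    cutoff: float = 2.0
    atom_selection: str = "all"
    n_images: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise PoseError("clash cutoff must be positive")
        if self.atom_selection not in ("all", "heavy"):
            raise PoseError("atom_selection must be 'all' or 'heavy'")
        if self.n_images < 1:
            raise PoseError("n_images must be >= 1")


def _selected_coords(pose: LigandPose, cfg: ClashConfig) -> np.ndarray:
    coords = pose.coords(heavy_only=(cfg.atom_selection == "heavy"))
    if coords.shape[0] == 0:
        raise PoseError(
            f"pose {pose.mol_id!r}: empty atom selection {cfg.atom_selection!r}"
        )
    return coords


def symmetry_clash_check(
    pose: LigandPose, op: AffineOperator, cfg: ClashConfig = ClashConfig()
) -> tuple[bool, float]:
    """Check a pose against its own symmetry image(s).

    Returns ``(passes, min_distance)`` where ``min_distance`` is the smallest
    distance between any original atom and any image atom over images
    ``k = 1 .. n_images`` (the −k images give identical distances by
    symmetry, so only positive powers are evaluated).

    The all-pairs distance matrix is evaluated vectorized with the component
    squares added in fixed order; a k-d tree (and even cdist / an axis-sum)
    is deliberately avoided because their different rounding paths can
    disagree with the plain ``sqrt(dx²+dy²+dz²)`` double loop in the last
    bit, and the verdict must match it exactly.
    """
    coords = _selected_coords(pose, cfg)
    min_dist = np.inf
    current = coords
    for _ in range(cfg.n_images):
        current = op.apply(current)
        diff = coords[:, None, :] - current[None, :, :]
        dx, dy, dz = diff[..., 0], diff[..., 1], diff[..., 2]
        d2 = dx * dx + dy * dy + dz * dz
        min_dist = min(min_dist, float(np.sqrt(d2.min())))
    return bool(min_dist >= cfg.cutoff), min_dist


def build_stack(
    pose: LigandPose, op: AffineOperator, n_up: int, n_down: int
) -> list[LigandPose]:
    """Generate the symmetry stack ``op^k(pose)`` for k in [-n_down, +n_up].

    The k=0 element is the input pose object itself.
    """
    if n_up < 0 or n_down < 0:
        raise PoseError("n_up and n_down must be >= 0")
    stack = []
    for k in range(-n_down, n_up + 1):
        stack.append(pose if k == 0 else pose.transformed(op.power(k)))
    return stack


def fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points; returns (centroid, unit normal)."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise PlaneFitError("need at least 3 atoms to fit a plane")
    center = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - center)
    # collinear points: second singular value vanishes
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise PlaneFitError("ring atoms are collinear; plane is undefined")
    return center, Vt[2]


def interplanar_distance(
    pose: LigandPose, op: AffineOperator, ring_atoms: Sequence[int]
) -> float:
    """Distance from the ring plane of the pose to the image ring centroid."""
    idx = list(ring_atoms)
    if len(idx) < 3:
        raise PlaneFitError("ring selection must contain at least 3 atoms")
    coords = pose.coords()[idx]
    center, normal = fit_plane(coords)
    image_centroid = op.apply(coords).mean(axis=0)
    return float(abs((image_centroid - center) @ normal))


def pose_rmsd(
    pose_a: LigandPose,
    pose_b: LigandPose,
    heavy_only: bool = True,
    atom_map: Optional[Sequence[tuple[int, int]]] = None,
) -> float:
    """In-place RMSD between two poses of the same molecule (no superposition)."""
    if atom_map is None:
        if len(pose_a.atoms) != len(pose_b.atoms):
            raise PoseError(
                f"atom count mismatch: {pose_a.mol_id!r} has {len(pose_a.atoms)}, "
                f"{pose_b.mol_id!r} has {len(pose_b.atoms)}; supply atom_map"
            )
        mismatched = [
            i
            for i, (a, b) in enumerate(zip(pose_a.atoms, pose_b.atoms))
            if a.element.upper() != b.element.upper()
        ]
        if mismatched:
            raise PoseError(f"element mismatch at atom indices {mismatched}")
        atom_map = [(i, i) for i in range(len(pose_a.atoms))]
    pairs = [
        (i, j)
        for i, j in atom_map
        if not heavy_only or (pose_a.atoms[i].is_heavy and pose_b.atoms[j].is_heavy)
    ]
    if not pairs:
        raise PoseError("no mapped atoms left after heavy-atom filtering")
    ca = np.array([pose_a.atoms[i].coord for i, _ in pairs])
    cb = np.array([pose_b.atoms[j].coord for _, j in pairs])
    diff = ca - cb
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
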