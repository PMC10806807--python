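"""Screw-symmetry operators for helical fibrils.

A fibril relates consecutive monomers by a single rigid screw motion:
a rotation (*twist*) about an axis combined with a translation (*rise*)
along it.  This module represents that motion as an affine operator
``x' = R @ x + t`` (column-vector convention), derives it from a stack of
monomers by least-squares superposition, and converts between the matrix
form and the geometric screw parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    CorrespondenceError,
    DegenerateOperatorError,
    InsufficientInputError,
    OperatorError,
)

__all__ = [
    "AffineOperator",
    "ScrewParameters",
    "Atom",
    "Chain",
    "FibrilStructure",
    "derive_operator",
    "decompose_screw",
    "screw_to_operator",
    "kabsch",
]

_ORTHO_TOL = 1e-6
BACKBONE_ATOMS = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# Operator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineOperator:
    """Proper rigid motion ``x' = rotation @ x + translation``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Proper rotation matrix (orthogonal, determinant +1).
    translation : (3,) ndarray
        Translation in Å applied after the rotation.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(-1)
        if R.shape != (3, 3):
            raise OperatorError(f"rotation must be 3x3, got {R.shape}")
        if t.shape != (3,):
            raise OperatorError(f"translation must be length 3, got {t.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise OperatorError("operator contains non-finite entries")
        if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHO_TOL:
            raise OperatorError("rotation is not orthogonal within 1e-6")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise OperatorError("rotation determinant is not +1 (improper)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- algebra ------------------------------------------------------------

    @classmethod
    def identity(cls) -> "AffineOperator":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(coords, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "AffineOperator") -> "AffineOperator":
        """Return the operator equivalent to applying ``other`` first, then self."""
        return AffineOperator(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "AffineOperator":
        Rinv = self.rotation.T
        return AffineOperator(Rinv, -Rinv @ self.translation)

    def power(self, k: int) -> "AffineOperator":
        """k-fold composition; k may be negative or zero."""
        if not isinstance(k, (int, np.integer)):
            raise OperatorError("power exponent must be an integer")
        if k == 0:
            return AffineOperator.identity()
        base = self if k > 0 else self.invert()
        out = base
        for _ in range(abs(int(k)) - 1):
            out = out.compose(base)
        return out

    def __matmul__(self, other: "AffineOperator") -> "AffineOperator":
        return self.compose(other)

    def __pow__(self, k: int) -> "AffineOperator":
        return self.power(k)

    def is_close(self, other: "AffineOperator", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    # -- serialization ------------------------------------------------------

    def to_matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AffineOperator":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise OperatorError(f"homogeneous matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise OperatorError("bottom row of homogeneous matrix must be [0,0,0,1]")
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self) -> str:
        return json.dumps({"matrix": self.to_matrix().tolist()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AffineOperator":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise OperatorError(f"operator JSON is unparseable: {exc}") from exc
        if "matrix" not in payload:
            raise OperatorError('operator JSON must contain a "matrix" key')
        return cls.from_matrix(np.asarray(payload["matrix"], dtype=float))


# ---------------------------------------------------------------------------
# Screw parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrewParameters:
    """Geometric description of a screw motion.

    ``axis`` is a unit vector oriented so that ``rise >= 0``; ``twist_deg``
    is signed by the right-hand rule about that axis; ``axis_point`` is the
    point on the screw axis with zero component along the axis direction.
    """

    axis: np.ndarray
    twist_deg: float
    rise: float
    axis_point: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if abs(n - 1.0) > 1e-9:
            raise OperatorError("screw axis must be a unit vector")
        object.__setattr__(self, "axis", a)
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3)
        )


def screw_to_operator(params: ScrewParameters) -> AffineOperator:
    """Reconstruct the affine operator from screw parameters."""
    axis = params.axis
    R = Rotation.from_rotvec(axis * np.deg2rad(params.twist_deg)).as_matrix()
    t = params.rise * axis + (np.eye(3) - R) @ params.axis_point
    return AffineOperator(R, t)


def decompose_screw(op: AffineOperator, angle_tol: float = 1e-9) -> ScrewParameters:
    """Extract axis, twist, rise, and a point on the axis from an operator.

    For a (near-)identity rotation the axis is taken along the translation;
    an operator with neither rotation nor translation is degenerate.
    """
    rotvec = Rotation.from_matrix(op.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    t = op.translation

    if angle <= angle_tol:
        tnorm = float(np.linalg.norm(t))
        if tnorm <= angle_tol:
            raise DegenerateOperatorError(
                "identity operator has no screw axis (zero rotation and translation)"
            )
        axis = t / tnorm
        return ScrewParameters(axis=axis, twist_deg=0.0, rise=tnorm,
                               axis_point=np.zeros(3))

    axis = rotvec / angle
    twist_deg = float(np.rad2deg(angle))
    rise = float(t @ axis)
    if rise < 0:
        axis = -axis
        twist_deg = -twist_deg
        rise = -rise

    # In-plane fixed point: (I - R) p = t_perp, solved in the plane ⊥ axis.
    t_perp = t - (t @ axis) * axis
    A = np.eye(3) - op.rotation
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - (p @ axis) * axis
    return ScrewParameters(axis=axis, twist_deg=twist_deg, rise=rise, axis_point=p)


# ---------------------------------------------------------------------------
# Fibril structure
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom record of a protein monomer."""

    name: str
    element: str
    res_id: int
    res_name: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)


@dataclass
class Chain:
    """One monomer: an ordered list of atom records with a chain identifier."""

    chain_id: str
    atoms: list[Atom]

    def residue_signature(self) -> tuple[tuple[int, str], ...]:
        seen: dict[int, str] = {}
        order: list[int] = []
        for a in self.atoms:
            if a.res_id not in seen:
                seen[a.res_id] = a.res_name
                order.append(a.res_id)
        return tuple((rid, seen[rid]) for rid in order)

    def residue_names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.residue_signature())

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def select(self, atom_names: Sequence[str]) -> "Chain":
        wanted = set(atom_names)
        return Chain(self.chain_id, [a for a in self.atoms if a.name in wanted])


@dataclass
class FibrilStructure:
    """Protein chains grouped into protofilaments.

    ``protofilaments`` maps a protofilament label to the list of chain IDs
    in stacking order (bottom to top along the fibril axis).
    """

    chains: list[Chain]
    protofilaments: dict[str, list[str]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def protofilament_chains(self, label: str) -> list[Chain]:
        if label not in self.protofilaments:
            raise KeyError(f"no protofilament {label!r}; have {sorted(self.protofilaments)}")
        return [self.chain(cid) for cid in self.protofilaments[label]]

    def validate(self) -> None:
        """Check that consecutive monomers in each protofilament correspond."""
        for label, chain_ids in self.protofilaments.items():
            chains = [self.chain(cid) for cid in chain_ids]
            for prev, nxt in zip(chains, chains[1:]):
                if prev.residue_names() != nxt.residue_names():
                    raise CorrespondenceError(
                        f"protofilament {label!r}: chains {prev.chain_id!r} and "
                        f"{nxt.chain_id!r} have different residue sequences"
                    )


# ---------------------------------------------------------------------------
# Superposition / derivation
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with Q ≈ R P + t."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise InsufficientInputError("point sets must be matching (N, 3) arrays")
    if P.shape[0] < 3:
        raise InsufficientInputError("need at least 3 points for superposition")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a matrix to the closest proper rotation (chordal mean step)."""
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def _correspondence_coords(
    prev: Chain, nxt: Chain, atom_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if prev.residue_names() != nxt.residue_names():
        raise CorrespondenceError(
            f"chains {prev.chain_id!r} and {nxt.chain_id!r} have different "
            "residue sequences; cannot build atom correspondence"
        )
    wanted = set(atom_names)

    def keyed(chain: Chain) -> dict[tuple[int, int, str], np.ndarray]:
        # key on (ordinal residue index, atom name) so numbering offsets don't matter
        rid_order: dict[int, int] = {}
        out = {}
        for a in chain.atoms:
            if a.res_id not in rid_order:
                rid_order[a.res_id] = len(rid_order)
            if a.name in wanted:
                out[(rid_order[a.res_id], 0, a.name)] = a.coord
        return out

    ka, kb = keyed(prev), keyed(nxt)
    common = sorted(set(ka) & set(kb))
    if len(common) < 3:
        raise CorrespondenceError(
            f"chains {prev.chain_id!r}/{nxt.chain_id!r}: fewer than 3 shared "
            f"atoms among {sorted(wanted)}"
        )
    P = np.array([ka[k] for k in common])
    Q = np.array([kb[k] for k in common])
    return P, Q


def derive_operator(
    fibril: FibrilStructure,
    protofilament: str,
    atom_names: Sequence[str] = ("CA",),
) -> AffineOperator:
    """Derive the fibril screw operator from one protofilament.

    Superposes each consecutive monomer pair (least-squares, proper
    rotation), averages the rotations via the chordal mean, then re-solves
    the translation of every pair against the mean rotation and averages.

    Parameters
    ----------
    fibril : FibrilStructure
    protofilament : str
        Label of the protofilament whose stacked monomers define the operator.
    atom_names : sequence of str
        Atom names used for correspondence; default alpha-carbons only.
    """
    chains = fibril.protofilament_chains(protofilament)
    if len(chains) < 2:
        raise InsufficientInputError(
            f"protofilament {protofilament!r} has {len(chains)} monomer(s); "
            "need at least 2 to derive an operator"
        )
    pairs = [
        _correspondence_coords(prev, nxt, atom_names)
        for prev, nxt in zip(chains, chains[1:])
    ]
    rotations = []
    for P, Q in pairs:
        R, _ = kabsch(P, Q)
        rotations.append(R)
    R_mean = _nearest_rotation(np.mean(rotations, axis=0))
    translations = [Q.mean(axis=0) - R_mean @ P.mean(axis=0) for P, Q in pairs]
    return AffineOperator(R_mean, np.mean(translations, axis=0))


def superposition_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD of Q vs the optimal rigid superposition of P onto Q."""
    R, t = kabsch(P, Q)
    diff = (np.asarray(P) @ R.T + t) - np.asarray(Q)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def group_chains_by_contact(
    chains: Iterable[Chain], contact_cutoff: float = 6.0
) -> dict[str, list[str]]:
    """Auto-group chains into protofilaments by alpha-carbon contact.

    Chains whose minimum inter-chain CA distance is below ``contact_cutoff``
    are clustered together; each cluster is ordered by the projection of the
    chain centroid onto the global principal axis of all CA coordinates.
    """
    chains = list(chains)
    ca_sets = []
    for c in chains:
        ca = np.array([a.coord for a in c.atoms if a.name == "CA"], dtype=float)
        if ca.size == 0:
            ca = c.coords()
        ca_sets.append(ca)

    n = len(chains)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    from scipy.spatial.distance import cdist

    for i in range(n):
        for j in range(i + 1, n):
            if cdist(ca_sets[i], ca_sets[j]).min() < contact_cutoff:
                parent[find(i)] = find(j)

    all_ca = np.vstack(ca_sets)
    centered = all_ca - all_ca.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    groups: dict[str, list[str]] = {}
    ordered_roots = sorted(
        clusters, key=lambda r: min(chains[i].chain_id for i in clusters[r])
    )
    for gi, root in enumerate(ordered_roots):
        members = clusters[root]
        members.sort(key=lambda i: float(ca_sets[i].mean(axis=0) @ axis))
        groups[f"P{gi + 1}"] = [chains[i].chain_id for i in members]
    return groups
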