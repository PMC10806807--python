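"""Readers and writers for the formats the toolkit touches.

Structures are PDB (via biotite); poses are SDF (via RDKit) or MOL2
(TRIPOS records parsed directly so that SYBYL atom-type labels survive
verbatim — RDKit normalizes them away); operators are JSON; screens and
verdicts are CSV; boundary pseudo-atoms are plain xyzr text.

All writers are deterministic: identical inputs produce byte-identical
files (no timestamps in data files).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FileFormatError, MetricError
from .geometry import (
    Atom,
    AffineOperator,
    Chain,
    FibrilStructure,
    group_chains_by_contact,
)
from .metrics import ScreenRecord
from .stacking import LigandAtom, LigandPose

__all__ = [
    "read_structure",
    "write_structure",
    "read_poses",
    "write_poses_sdf",
    "write_stack_pdb",
    "write_xyzr",
    "read_operator",
    "write_operator",
    "read_screen_csv",
    "write_screen_csv",
]


# ---------------------------------------------------------------------------
# Structures (PDB)
# ---------------------------------------------------------------------------

def read_structure(
    path,
    protofilaments: Optional[dict[str, list[str]]] = None,
    contact_cutoff: float = 6.0,
) -> FibrilStructure:
    """Read a PDB file into a FibrilStructure.

    Altloc policy: keep the first (A) location.  Hydrogens are kept when
    present.  Protofilament assignment comes from ``protofilaments`` (label
    -> ordered chain IDs) or, when omitted, from contact-based auto-grouping.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise FileFormatError(f"cannot parse PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise FileFormatError(f"{path}: no atoms found")

    import biotite.structure as struc

    protein_mask = struc.filter_amino_acids(arr)
    if not protein_mask.any():
        raise FileFormatError(f"{path}: no protein chains found")
    arr = arr[protein_mask]

    chains: list[Chain] = []
    order: list[str] = []
    grouped: dict[str, list[Atom]] = {}
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        if cid not in grouped:
            grouped[cid] = []
            order.append(cid)
        elem = str(arr.element[i]).capitalize()
        grouped[cid].append(
            Atom(
                name=str(arr.atom_name[i]),
                element=elem,
                res_id=int(arr.res_id[i]),
                res_name=str(arr.res_name[i]),
                coord=np.array(arr.coord[i], dtype=float),
            )
        )
    chains = [Chain(cid, grouped[cid]) for cid in order]

    if protofilaments is None:
        protofilaments = group_chains_by_contact(chains, contact_cutoff)
    return FibrilStructure(chains=chains, protofilaments=protofilaments)


def write_structure(fibril: FibrilStructure, path) -> None:
    """Write a FibrilStructure as a single-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = sum(len(c.atoms) for c in fibril.chains)
    arr = struc.AtomArray(n)
    i = 0
    for chain in fibril.chains:
        if len(chain.chain_id) > 1:
            raise FileFormatError(
                f"chain ID {chain.chain_id!r} does not fit the PDB chain field; "
                "reduce extension copies"
            )
        for a in chain.atoms:
            arr.chain_id[i] = chain.chain_id
            arr.res_id[i] = a.res_id
            arr.res_name[i] = a.res_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element.upper()
            arr.coord[i] = a.coord
            arr.hetero[i] = False
            i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Poses (SDF via RDKit, MOL2 parsed directly)
# ---------------------------------------------------------------------------

def _unique_ids(raw_ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for rid in raw_ids:
        if rid in seen:
            seen[rid] += 1
            out.append(f"{rid}_{seen[rid]}")
        else:
            seen[rid] = 0
            out.append(rid)
    return out


def _read_sdf(path: Path) -> list[LigandPose]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    poses = []
    raw_ids = []
    n_skipped = 0
    for idx, mol in enumerate(supplier):
        if mol is None or mol.GetNumAtoms() == 0:
            n_skipped += 1
            continue
        conf = mol.GetConformer()
        atoms = []
        for ai in range(mol.GetNumAtoms()):
            rd_atom = mol.GetAtomWithIdx(ai)
            pos = conf.GetAtomPosition(ai)
            elem = rd_atom.GetSymbol()
            atoms.append(
                LigandAtom(elem, f"{elem}{ai + 1}", np.array([pos.x, pos.y, pos.z]))
            )
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
            for b in mol.GetBonds()
        ]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        raw_ids.append(name.strip() or f"pose_{idx + 1}")
        poses.append((atoms, bonds))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} empty/unreadable record(s)",
                      stacklevel=3)
    ids = _unique_ids(raw_ids)
    return [LigandPose(mid, atoms, bonds) for mid, (atoms, bonds) in zip(ids, poses)]


def _read_mol2(path: Path) -> list[LigandPose]:
    text = path.read_text()
    records = text.split("@<TRIPOS>MOLECULE")
    poses = []
    raw_ids = []
    n_skipped = 0
    for idx, rec in enumerate(records[1:], start=1):
        lines = rec.splitlines()
        name = lines[1].strip() if len(lines) > 1 else ""
        atoms: list[LigandAtom] = []
        bonds: list[tuple[int, int, int]] = []
        section = None
        for line in lines:
            if line.startswith("@<TRIPOS>"):
                section = line.strip()
                continue
            if not line.strip():
                continue
            if section == "@<TRIPOS>ATOM":
                fields = line.split()
                if len(fields) < 6:
                    raise FileFormatError(f"{path}: malformed ATOM line: {line!r}")
                sybyl = fields[5]
                elem = sybyl.split(".")[0]
                charge = float(fields[8]) if len(fields) > 8 else None
                atoms.append(
                    LigandAtom(
                        element=elem,
                        name=fields[1],
                        coord=np.array([float(fields[2]), float(fields[3]),
                                        float(fields[4])]),
                        charge=charge,
                        vdw_type=sybyl,
                    )
                )
            elif section == "@<TRIPOS>BOND":
                fields = line.split()
                if len(fields) >= 4:
                    order = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1, "du": 1}.get(
                        fields[3], 1
                    )
                    bonds.append((int(fields[1]) - 1, int(fields[2]) - 1, order))
        if not atoms:
            n_skipped += 1
            continue
        raw_ids.append(name or f"pose_{idx}")
        poses.append((atoms, bonds))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} empty record(s)", stacklevel=3)
    if not poses:
        raise FileFormatError(f"{path}: no molecule records found")
    ids = _unique_ids(raw_ids)
    return [LigandPose(mid, atoms, bonds) for mid, (atoms, bonds) in zip(ids, poses)]


def read_poses(path, fmt: Optional[str] = None) -> list[LigandPose]:
    """Read ligand poses from SDF or MOL2 (dispatch by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pose file not found: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("sdf", "sd", "mol"):
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise FileFormatError(f"unknown pose format {fmt!r} for {path}")


def write_poses_sdf(poses: Sequence[LigandPose], path) -> None:
    """Write poses as a multi-record SDF (one record per pose)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    blocks = []
    for pose in poses:
        mol = Chem.RWMol()
        for a in pose.atoms:
            rd = Chem.Atom(a.element)
            rd.SetNoImplicit(True)
            mol.AddAtom(rd)
        conf = Chem.Conformer(len(pose.atoms))
        for i, a in enumerate(pose.atoms):
            conf.SetAtomPosition(i, Point3D(*a.coord))
        bond_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                      3: Chem.BondType.TRIPLE}
        for i, j, order in pose.bonds:
            mol.AddBond(i, j, bond_types.get(order, Chem.BondType.SINGLE))
        mol.AddConformer(conf)
        mol.SetProp("_Name", pose.mol_id)
        mol.UpdatePropertyCache(strict=False)
        blocks.append(Chem.MolToMolBlock(mol, kekulize=False) + "$$$$\n")
    Path(path).write_text("".join(blocks))


def write_stack_pdb(stack: Sequence[LigandPose], path) -> None:
    """Write a symmetry stack as a multi-model PDB (MODEL/ENDMDL per member)."""
    lines = []
    for model_no, pose in enumerate(stack, start=1):
        lines.append(f"MODEL     {model_no:4d}")
        for i, a in enumerate(pose.atoms, start=1):
            name = a.name[:4]
            lines.append(
                f"HETATM{i:5d} {name:<4s} LIG A   1    "
                f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"  1.00  0.00          {a.element.upper():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyzr(pseudoatoms: np.ndarray, path) -> None:
    """Write an (N, 4) xyzr array as 'x y z radius' lines."""
    rows = np.asarray(pseudoatoms, dtype=float).reshape(-1, 4)
    with open(path, "w") as fh:
        for x, y, z, r in rows:
            fh.write(f"{x:12.6f} {y:12.6f} {z:12.6f} {r:8.4f}\n")


# ---------------------------------------------------------------------------
# Operators, screens
# ---------------------------------------------------------------------------

def read_operator(path) -> AffineOperator:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"operator file not found: {path}")
    return AffineOperator.from_json(path.read_text())


def write_operator(op: AffineOperator, path) -> None:
    Path(path).write_text(op.to_json() + "\n")


def read_screen_csv(path) -> list[ScreenRecord]:
    """Read a screen CSV (columns id, score, label).

    Rows with an empty score are treated as clash-rejected molecules: they
    keep their input order and are ranked after every scored molecule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"screen file not found: {path}")
    df = pd.read_csv(path)
    required = {"id", "score", "label"}
    if not required.issubset(df.columns):
        raise FileFormatError(
            f"{path}: screen CSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score")
        scored = pd.notna(score)
        label = str(getattr(row, "label")).strip().lower()
        if label not in ("active", "decoy"):
            raise MetricError(f"{path}: bad label {label!r} for id {getattr(row, 'id')!r}")
        records.append(
            ScreenRecord(
                str(getattr(row, "id")),
                float(score) if scored else None,
                label,
                scored=scored,
            )
        )
    n_unscored = sum(1 for r in records if not r.scored)
    if n_unscored:
        warnings.warn(
            f"{path}: {n_unscored} unscored molecule(s) ranked last", stacklevel=2
        )
    return records


def write_screen_csv(records: Sequence[ScreenRecord], path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.mol_id for r in records],
            "score": [r.score if r.scored else "" for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)
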