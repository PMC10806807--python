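"""Periodic extension of fibril structures and dielectric-boundary export.

Deposited fibril structures contain only a handful of monomers; docking
against them risks edge effects. Applying the screw operator (and its
inverse) blockwise generates a longer fibril with the deposited
coordinates untouched at its center. The heavy atoms of a ligand stack
can likewise be exported as pseudo-atoms for downstream dielectric-grid
preparation.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SymstackError
from .geometry import (
    Atom,
    AffineOperator,
    Chain,
    FibrilStructure,
    superposition_rmsd,
)
from .stacking import LigandPose, build_stack

__all__ = ["ExtendedFibril", "extend_fibril", "boundary_pseudoatoms"]

DEFAULT_PSEUDOATOM_RADIUS = 1.9

_CHAIN_ID_POOL = (
    list(string.ascii_uppercase) + list(string.ascii_lowercase) + list(string.digits)
)


@dataclass
class ExtendedFibril:
    """Original structure plus operator-generated copies.

    ``provenance`` maps each chain ID of the extended structure to
    ``(template_chain_id, k)`` where ``k`` is the operator power that
    produced it (0 for deposited chains).
    """

    original: FibrilStructure
    structure: FibrilStructure
    provenance: dict[str, tuple[str, int]]

    @property
    def chains(self) -> list[Chain]:
        return self.structure.chains


def _fresh_chain_ids(n_needed: int, taken: set[str]) -> list[str]:
    ids = []
    for cid in _CHAIN_ID_POOL:
        if cid not in taken:
            ids.append(cid)
            if len(ids) == n_needed:
                return ids
    # fall back to two-character segment-style IDs
    for a in _CHAIN_ID_POOL:
        for b in _CHAIN_ID_POOL:
            cid = a + b
            if cid not in taken:
                ids.append(cid)
                if len(ids) == n_needed:
                    return ids
    raise SymstackError(
        "chain-ID namespace exhausted; write output with segment IDs instead"
    )


def _transformed_chain(chain: Chain, op: AffineOperator, new_id: str) -> Chain:
    coords = op.apply(chain.coords())
    atoms = [
        Atom(a.name, a.element, a.res_id, a.res_name, c)
        for a, c in zip(chain.atoms, coords)
    ]
    return Chain(new_id, atoms)


def _check_operator_consistency(
    fibril: FibrilStructure, op: AffineOperator, threshold: float
) -> None:
    for label, chain_ids in fibril.protofilaments.items():
        chains = [fibril.chain(cid) for cid in chain_ids]
        for prev, nxt in zip(chains, chains[1:]):
            ca_prev = np.array([a.coord for a in prev.atoms if a.name == "CA"])
            ca_next = np.array([a.coord for a in nxt.atoms if a.name == "CA"])
            if ca_prev.shape != ca_next.shape or ca_prev.shape[0] < 3:
                continue
            # the stacking order may run opposite to the operator direction;
            # either mapping direction counts as consistent
            rmsd = min(
                float(np.sqrt(np.mean(
                    np.sum((op.apply(ca_prev) - ca_next) ** 2, axis=1)))),
                float(np.sqrt(np.mean(
                    np.sum((op.apply(ca_next) - ca_prev) ** 2, axis=1)))),
            )
            if rmsd > threshold:
                warnings.warn(
                    f"operator maps chain {prev.chain_id!r} onto {nxt.chain_id!r} "
                    f"with RMSD {rmsd:.2f} Å (> {threshold} Å); operator may not "
                    "match this fibril",
                    stacklevel=3,
                )
                return


def extend_fibril(
    fibril: FibrilStructure,
    op: AffineOperator,
    copies_up: int,
    copies_down: int,
    residual_threshold: float = 1.0,
) -> ExtendedFibril:
    """Extend every protofilament blockwise by powers of the operator.

    A protofilament of n monomers gains ``copies_up`` whole-stack copies
    above (powers +n, +2n, ...) and ``copies_down`` below, so each copy
    preserves the deposited per-monomer coordinate differences verbatim.
    """
    if copies_up < 0 or copies_down < 0:
        raise SymstackError("copy counts must be >= 0")
    _check_operator_consistency(fibril, op, residual_threshold)

    taken = {c.chain_id for c in fibril.chains}
    n_new = sum(
        len(chain_ids) * (copies_up + copies_down)
        for chain_ids in fibril.protofilaments.values()
    )
    fresh = iter(_fresh_chain_ids(n_new, taken) if n_new else [])

    new_chains: list[Chain] = list(fibril.chains)
    provenance: dict[str, tuple[str, int]] = {
        c.chain_id: (c.chain_id, 0) for c in fibril.chains
    }
    new_protofilaments: dict[str, list[str]] = {}

    for label, chain_ids in fibril.protofilaments.items():
        n = len(chain_ids)
        blocks: list[tuple[int, list[str]]] = []
        for b in range(-copies_down, copies_up + 1):
            if b == 0:
                blocks.append((0, list(chain_ids)))
                continue
            power = b * n
            block_op = op.power(power)
            block_ids = []
            for cid in chain_ids:
                new_id = next(fresh)
                new_chains.append(
                    _transformed_chain(fibril.chain(cid), block_op, new_id)
                )
                provenance[new_id] = (cid, power)
                block_ids.append(new_id)
            blocks.append((b, block_ids))
        blocks.sort(key=lambda kv: kv[0])
        new_protofilaments[label] = [cid for _, ids in blocks for cid in ids]

    extended = FibrilStructure(chains=new_chains, protofilaments=new_protofilaments)
    return ExtendedFibril(original=fibril, structure=extended, provenance=provenance)


def boundary_pseudoatoms(
    pose: LigandPose,
    op: AffineOperator,
    n_up: int,
    n_down: int,
    radius: float = DEFAULT_PSEUDOATOM_RADIUS,
) -> np.ndarray:
    """Heavy-atom pseudo-atoms of the ligand stack, as an (N, 4) xyzr array."""
    stack = build_stack(pose, op, n_up=n_up, n_down=n_down)
    rows = []
    for member in stack:
        for coord in member.coords(heavy_only=True):
            rows.append([coord[0], coord[1], coord[2], radius])
    return np.array(rows, dtype=float)
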