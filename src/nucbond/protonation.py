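"""Idealized hydrogen placement on donor heavy atoms.

X-ray structures at the resolutions considered here do not resolve
hydrogens, so every donor hydrogen is placed from the surrounding heavy
atoms using textbook covalent geometry:

* bond lengths N-H 1.00 Å, O-H 0.96 Å, S-H 1.34 Å;
* sp2 donors (backbone amide, guanidinium, carboxamide, ring N-H,
  nucleobase amino groups) get hydrogens at fixed idealized positions in
  the plane of their heavy-atom frame;
* sp3 rotors (hydroxyl, sulfhydryl, ammonium) have a free torsion: their
  hydrogen lies on the tetrahedral cone about the bond to the parent
  heavy atom, and the rotamer is chosen per candidate acceptor as the
  cone point closest to that acceptor (the most favorable rotamer).

Placements for donors whose frame atoms are missing from the model are
skipped and logged; gaps are never fatal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import Atom, Chain, Residue, Structure
from .roles import RoleDictionary, RoleEntry

logger = logging.getLogger(__name__)

BOND_LENGTH = {"N": 1.00, "O": 0.96, "S": 1.34}
SP2_ANGLE = math.radians(120.0)
TETRAHEDRAL = math.acos(-1.0 / 3.0)  # 109.471 degrees


@dataclass(frozen=True)
class HydrogenPlacement:
    """One inferred hydrogen on a donor heavy atom.

    ``fixed`` is False for rotor donors, whose recorded position is the
    canonical rotamer (torsion 180 degrees from the second frame atom) and
    is re-optimized per acceptor by the detection engine.
    """

    parent: object  # AtomRef or Atom of the donor heavy atom
    position: np.ndarray
    fixed: bool = True


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry: zero-length frame vector")
    return v / n


def bisector_hydrogen(donor: np.ndarray, a1: np.ndarray, a2: np.ndarray, length: float) -> np.ndarray:
    """Single sp2 H on the external bisector of the a1-donor-a2 frame."""
    direction = _unit(_unit(donor - a1) + _unit(donor - a2))
    return donor + length * direction


def amide_hydrogens(
    donor: np.ndarray, parent: np.ndarray, ref: np.ndarray, length: float
) -> list[np.ndarray]:
    """Two sp2 H in the (ref, parent, donor) plane, 120 deg off the N-parent bond."""
    base = _unit(donor - parent)
    normal = np.cross(parent - ref, donor - parent)
    perp = _unit(np.cross(_unit(normal), base))
    c, s = math.cos(math.pi - SP2_ANGLE), math.sin(math.pi - SP2_ANGLE)
    return [donor + length * (c * base + s * perp), donor + length * (c * base - s * perp)]


def rotor_cone_point(
    donor: np.ndarray, r1: np.ndarray, r2: np.ndarray, length: float, phi: float
) -> np.ndarray:
    """Point on the sp3 cone about the r1->donor axis at torsion ``phi``.

    ``phi`` is the dihedral measured from r2, so ``phi = pi`` is the
    canonical anti rotamer.
    """
    axis = _unit(donor - r1)
    e1 = r2 - r1
    e1 = e1 - np.dot(e1, axis) * axis
    e1 = _unit(e1)
    e2 = np.cross(axis, e1)
    half = math.pi - TETRAHEDRAL  # angle between H direction and the axis
    direction = math.cos(half) * axis + math.sin(half) * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return donor + length * direction


def rotor_hydrogen_toward(
    donor: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
    acceptor: np.ndarray,
    length: float,
) -> np.ndarray:
    """The cone point minimizing the H-acceptor distance (closed form).

    The optimal torsion matches the acceptor's azimuth about the rotor
    axis.  If the acceptor lies on the axis every cone point is
    equidistant and the canonical anti rotamer (torsion 180 deg) is
    returned.
    """
    axis = _unit(donor - r1)
    e1 = r2 - r1
    e1 = e1 - np.dot(e1, axis) * axis
    e1 = _unit(e1)
    e2 = np.cross(axis, e1)
    rel = acceptor - donor
    x, y = np.dot(rel, e1), np.dot(rel, e2)
    if x * x + y * y < 1e-18:
        return rotor_cone_point(donor, r1, r2, length, math.pi)
    return rotor_cone_point(donor, r1, r2, length, math.atan2(y, x))


def _frame_positions(
    chain: Chain, index: int, residue: Residue, entry: RoleEntry
) -> list[np.ndarray] | None:
    """Resolve the frame atom names of a donor entry to coordinates."""
    positions: list[np.ndarray] = []
    for token in entry.frame:
        if token == "C^-":
            if index == 0:
                return None
            prev = chain.residues[index - 1]
            atom = prev.find_atom("C")
            # require an actual peptide bond, not a chain break
            n = residue.find_atom("N")
            if atom is None or n is None or np.linalg.norm(atom.position - n.position) > 2.0:
                return None
            positions.append(atom.position)
        else:
            atom = residue.find_atom(token)
            if atom is None:
                return None
            positions.append(atom.position)
    return positions


def donor_is_terminal(chain: Chain, index: int, residue: Residue, atom_name: str) -> bool:
    """Whether an O3'/O5' is a free (terminal) hydroxyl rather than a bridge.

    O5' is terminal when its own residue has no phosphorus; O3' when no
    following residue contributes a phosphorus within bonding distance.
    """
    if atom_name == "O5'":
        return residue.find_atom("P") is None
    if atom_name == "O3'":
        o3 = residue.find_atom("O3'")
        if o3 is None:
            return False
        if index + 1 < len(chain.residues):
            nxt = chain.residues[index + 1].find_atom("P")
            if nxt is not None and np.linalg.norm(nxt.position - o3.position) < 2.0:
                return False
        return True
    return False


def infer_hydrogens(
    structure: Structure, roles: RoleDictionary
) -> dict[tuple, list[HydrogenPlacement]]:
    """Place hydrogens on every donor atom whose frame atoms are present.

    Returns a mapping from atom keys ``(chain id, seqid, icode, atom name)``
    to placements.  Fixed sp2 donors get their full set of idealized
    hydrogens; rotors get one canonical placement flagged ``fixed=False``.
    """
    from .model import AtomRef  # local import to avoid cycle in type hints

    placements: dict[tuple, list[HydrogenPlacement]] = {}
    for chain in structure.chains:
        for index, residue in enumerate(chain.residues):
            for atom in residue.atoms:
                entry = roles.lookup(residue.name, atom.name)
                if entry is None or not entry.donor:
                    continue
                if entry.donor_terminal_only and not donor_is_terminal(
                    chain, index, residue, atom.name
                ):
                    continue
                frame = _frame_positions(chain, index, residue, entry)
                if frame is None:
                    logger.info(
                        "no hydrogen for %s %s%s/%s: frame atoms missing",
                        residue.name, chain.id, residue.author_id, atom.name,
                    )
                    continue
                length = BOND_LENGTH.get(atom.element, BOND_LENGTH["N"])
                ref = AtomRef.of(chain, residue, atom)
                try:
                    if entry.donor_geometry == "bisector":
                        hs = [
                            HydrogenPlacement(
                                ref, bisector_hydrogen(atom.position, frame[0], frame[1], length)
                            )
                        ]
                    elif entry.donor_geometry == "amide2":
                        hs = [
                            HydrogenPlacement(ref, pos)
                            for pos in amide_hydrogens(atom.position, frame[0], frame[1], length)
                        ]
                    elif entry.donor_geometry in ("rotor", "rotor3"):
                        pos = rotor_cone_point(atom.position, frame[0], frame[1], length, math.pi)
                        hs = [HydrogenPlacement(ref, pos, fixed=False)]
                    else:
                        raise ValueError(f"unknown donor geometry {entry.donor_geometry!r}")
                except ValueError as exc:
                    logger.info("no hydrogen for %s/%s: %s", residue.name, atom.name, exc)
                    continue
                placements[(chain.id, residue.seqid, residue.icode, atom.name)] = hs
    return placements
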