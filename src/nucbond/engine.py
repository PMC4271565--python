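"""Hydrogen-bond detection between protein and nucleic-acid chains.

A donor-hydrogen...acceptor contact is accepted as a hydrogen bond when
all four geometric criteria hold (strict inequalities):

1. hydrogen-acceptor distance  H-A  < 2.5 Å,
2. donor-hydrogen-acceptor angle  D-H-A  > 90 deg,
3. donor-acceptor distance  D-A  < 3.9 Å,
4. hydrogen-acceptor-antecedent angle  H-A-AA  > 90 deg, for every
   antecedent atom present in the model.

Only inter-molecular bonds are considered: the donor and acceptor must lie
in chains of different molecule types (one protein, one DNA/RNA).  Water
never mediates.  Candidate pairs are found with a KD-tree at the D-A
cutoff; the result is required (and tested) to coincide with an all-pairs
scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, AtomRef, Chain, Residue, Structure
from .protonation import (
    BOND_LENGTH,
    HydrogenPlacement,
    donor_is_terminal,
    infer_hydrogens,
    rotor_hydrogen_toward,
)
from .roles import RoleDictionary, RoleEntry, default_roles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CriteriaConfig:
    """The four geometric thresholds, defaults as commonly used for H-bonds."""

    max_ha: float = 2.5
    min_dha_deg: float = 90.0
    max_da: float = 3.9
    min_haaa_deg: float = 90.0

    def __post_init__(self) -> None:
        if min(self.max_ha, self.min_dha_deg, self.max_da, self.min_haaa_deg) <= 0:
            raise ValueError("all criteria thresholds must be positive")
        if self.max_ha > self.max_da:
            raise ValueError("max_ha cannot exceed max_da")


@dataclass(frozen=True)
class HBond:
    """One donor->acceptor hydrogen bond with its measured geometry."""

    donor: AtomRef
    hydrogen: np.ndarray
    acceptor: AtomRef
    antecedent: str            # antecedent realizing the smallest H-A-AA angle
    d_ha: float
    d_da: float
    angle_dha: float
    angle_haaa: float          # smallest angle over all present antecedents
    donor_is_protein: bool = True

    def sort_key(self):
        return (
            self.donor.chain_id, self.donor.seqid, self.donor.icode, self.donor.atom_name,
            self.acceptor.chain_id, self.acceptor.seqid, self.acceptor.icode,
            self.acceptor.atom_name,
        )


@dataclass
class _Site:
    """A role-resolved atom site (donor or acceptor) ready for evaluation."""

    ref: AtomRef
    atom: Atom
    chain: Chain
    residue: Residue
    entry: RoleEntry
    is_protein: bool
    frame: list[np.ndarray] | None = None          # donor rotor frame positions
    placements: list[HydrogenPlacement] = field(default_factory=list)
    antecedents: list[tuple[str, np.ndarray]] = field(default_factory=list)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosine = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosine))))


def _acceptor_antecedents(
    chain: Chain, index: int, residue: Residue, entry: RoleEntry
) -> list[tuple[str, np.ndarray]]:
    """Resolve antecedent tokens to the atoms actually present."""
    out: list[tuple[str, np.ndarray]] = []
    for token in entry.antecedents:
        if token == "P^+":
            acc = residue.find_atom(entry.atom_name)
            if acc is None or index + 1 >= len(chain.residues):
                continue
            nxt = chain.residues[index + 1].find_atom("P")
            if nxt is not None and np.linalg.norm(nxt.position - acc.position) < 2.0:
                out.append(("P", nxt.position))
        else:
            atom = residue.find_atom(token)
            if atom is not None:
                out.append((token, atom.position))
    return out


def collect_sites(
    structure: Structure, roles: RoleDictionary | None = None
) -> tuple[list[_Site], list[_Site]]:
    """Gather role-resolved donor and acceptor sites in interface chains."""
    roles = roles or default_roles()
    placements = infer_hydrogens(structure, roles)
    donors: list[_Site] = []
    acceptors: list[_Site] = []
    for chain in structure.chains:
        if chain.kind not in ("protein", "dna", "rna"):
            continue
        is_protein = chain.kind == "protein"
        for index, residue in enumerate(chain.residues):
            for atom in residue.atoms:
                entry = roles.lookup(residue.name, atom.name)
                if entry is None:
                    continue
                ref = AtomRef.of(chain, residue, atom)
                key = (chain.id, residue.seqid, residue.icode, atom.name)
                if entry.donor and key in placements:
                    site = _Site(ref, atom, chain, residue, entry, is_protein)
                    site.placements = placements[key]
                    if entry.rotatable:
                        from .protonation import _frame_positions

                        site.frame = _frame_positions(chain, index, residue, entry)
                    donors.append(site)
                if entry.acceptor:
                    ants = _acceptor_antecedents(chain, index, residue, entry)
                    site = _Site(ref, atom, chain, residue, entry, is_protein)
                    site.antecedents = ants
                    acceptors.append(site)
    return donors, acceptors


def candidate_pairs(
    donors: list[_Site], acceptors: list[_Site], max_da: float
) -> list[tuple[int, int]]:
    """Cross-molecule (donor, acceptor) index pairs with D-A distance < max_da.

    Uses a KD-tree for the radius query; the strict inequality and the
    cross-molecule restriction are applied on top, so the result equals the
    all-pairs scan exactly.
    """
    if not donors or not acceptors:
        return []
    dpos = np.array([s.atom.position for s in donors])
    apos = np.array([s.atom.position for s in acceptors])
    tree = cKDTree(apos)
    pairs: list[tuple[int, int]] = []
    for i, neighbors in enumerate(tree.query_ball_point(dpos, r=max_da)):
        for j in neighbors:
            if donors[i].is_protein == acceptors[j].is_protein:
                continue
            if np.linalg.norm(dpos[i] - apos[j]) < max_da:  # strict
                pairs.append((i, j))
    return pairs


def evaluate_hbond(
    donor: _Site,
    acceptor: _Site,
    criteria: CriteriaConfig,
) -> HBond | None:
    """Apply the four criteria to one donor-acceptor pair.

    Rotor donors are re-protonated toward this acceptor (most favorable
    rotamer); among multiple qualifying hydrogens the one with the
    smallest H-A distance is recorded.  Criterion 4 must hold for every
    antecedent present; an acceptor with no antecedent in the model is
    rejected and logged.
    """
    dpos = donor.atom.position
    apos = acceptor.atom.position
    d_da = float(np.linalg.norm(dpos - apos))
    if d_da >= criteria.max_da:
        return None
    if not acceptor.antecedents:
        logger.info(
            "acceptor %s has no antecedent atoms in the model; pair rejected",
            acceptor.ref,
        )
        return None

    if donor.entry.rotatable and donor.frame is not None:
        length = BOND_LENGTH.get(donor.atom.element, BOND_LENGTH["N"])
        hydrogens = [
            rotor_hydrogen_toward(dpos, donor.frame[0], donor.frame[1], apos, length)
        ]
    else:
        hydrogens = [p.position for p in donor.placements]

    best: tuple[float, np.ndarray, float] | None = None
    for hpos in hydrogens:
        d_ha = float(np.linalg.norm(hpos - apos))
        if d_ha >= criteria.max_ha:
            continue
        angle_dha = _angle(dpos, hpos, apos)
        if angle_dha <= criteria.min_dha_deg:
            continue
        if best is None or d_ha < best[0]:
            best = (d_ha, hpos, angle_dha)
    if best is None:
        return None
    d_ha, hpos, angle_dha = best

    worst_angle = math.inf
    worst_name = ""
    for name, aa_pos in acceptor.antecedents:
        ang = _angle(hpos, apos, aa_pos)
        if ang < worst_angle:
            worst_angle, worst_name = ang, name
        if ang <= criteria.min_haaa_deg:
            return None
    return HBond(
        donor=donor.ref,
        hydrogen=hpos,
        acceptor=acceptor.ref,
        antecedent=worst_name,
        d_ha=d_ha,
        d_da=d_da,
        angle_dha=angle_dha,
        angle_haaa=worst_angle,
        donor_is_protein=donor.is_protein,
    )


def detect_interface_hbonds(
    structure: Structure,
    criteria: CriteriaConfig | None = None,
    roles: RoleDictionary | None = None,
) -> list[HBond]:
    """All protein<->nucleic-acid hydrogen bonds, deterministically sorted."""
    criteria = criteria or CriteriaConfig()
    has_protein = bool(structure.chains_of_kind("protein"))
    has_nucleic = bool(structure.chains_of_kind("dna", "rna"))
    if not (has_protein and has_nucleic):
        logger.warning(
            "%s: structure lacks a protein/nucleic-acid pair of chains",
            structure.entry_id,
        )
        return []
    donors, acceptors = collect_sites(structure, roles)
    bonds: list[HBond] = []
    for i, j in candidate_pairs(donors, acceptors, criteria.max_da):
        bond = evaluate_hbond(donors[i], acceptors[j], criteria)
        if bond is not None:
            bonds.append(bond)
    bonds.sort(key=HBond.sort_key)
    return bonds


def has_interface_hbond(
    structure: Structure,
    criteria: CriteriaConfig | None = None,
    roles: RoleDictionary | None = None,
) -> bool:
    """Complex retention rule: keep a complex iff it has >= 1 interface H-bond."""
    return bool(detect_interface_hbonds(structure, criteria, roles))
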