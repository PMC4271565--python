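"""Synthetic coordinate fixtures and an independent brute-force oracle.

Everything here serves testability without downloads:

* :func:`make_pair_fixture` emits PDB text containing one donor-acceptor
  pair with exactly the requested D-A distance, D-H-A angle and H-A-AA
  angle (within 1e-3), plus decoy residues placed far beyond the cutoff;
* :func:`make_random_fixture` scatters small protein and nucleic-acid
  motifs with seeded random placements, producing structures with an
  unpredictable mix of hits and near-misses around every threshold;
* :func:`brute_force_hbonds` re-detects hydrogen bonds with a plain
  all-pairs double loop and its own criterion arithmetic (no spatial
  index), serving as the oracle the accelerated engine must match;
* :func:`make_thr_cytidine_example` builds a synthetic reconstruction of
  the threonine-cytidine double-hydroxyl binding motif used as the
  package's worked example.

Fixtures are written as PDB text so they exercise the real parser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import CriteriaConfig, HBond, collect_sites
from .model import Atom, AtomRef, Chain, Residue, Structure
from .protonation import BOND_LENGTH, bisector_hydrogen, rotor_hydrogen_toward
from .roles import RoleDictionary, default_roles
from .structure_io import write_pdb


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) construction helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D with |CD| = bond, angle(B,C,D) and dihedral(A,B,C,D)."""
    theta, phi = math.radians(angle_deg), math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(phi),
         bond * math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sphere_directions(step_deg: float = 4.0):
    """Deterministic grid of unit vectors covering the sphere."""
    for theta in np.arange(step_deg / 2, 180.0, step_deg):
        st = math.sin(math.radians(theta))
        n_phi = max(1, int(round(360.0 * st / step_deg)))
        for k in range(n_phi):
            phi = math.radians(k * 360.0 / n_phi)
            yield np.array(
                [st * math.cos(phi), st * math.sin(phi), math.cos(math.radians(theta))]
            )


# ---------------------------------------------------------------------------
# residue motif templates (idealized local geometry, arbitrary orientation)
# ---------------------------------------------------------------------------

def _glycine_backbone(origin: np.ndarray) -> dict[str, np.ndarray]:
    n = origin
    ca = n + np.array([1.46, 0.0, 0.0])
    c = place_atom(n + np.array([0.0, 1.0, 0.0]), n, ca, 1.52, 110.0, 150.0)
    o = place_atom(n, ca, c, 1.23, 121.0, 0.0)
    return {"N": n, "CA": ca, "C": c, "O": o}


def _serine(origin: np.ndarray) -> dict[str, np.ndarray]:
    atoms = _glycine_backbone(origin)
    cb = place_atom(atoms["C"], atoms["CA"], atoms["N"], 1.53, 110.0, 120.0)
    # OG built off CB with CA as angle reference
    og = place_atom(atoms["N"], atoms["CA"], cb, 1.41, 109.5, 180.0)
    atoms.update({"CB": cb, "OG": og})
    return atoms


def _threonine(origin: np.ndarray) -> dict[str, np.ndarray]:
    atoms = _glycine_backbone(origin)
    cb = place_atom(atoms["C"], atoms["CA"], atoms["N"], 1.53, 110.0, 120.0)
    og1 = place_atom(atoms["N"], atoms["CA"], cb, 1.43, 109.5, 180.0)
    cg2 = place_atom(atoms["N"], atoms["CA"], cb, 1.52, 109.5, 60.0)
    atoms.update({"CB": cb, "OG1": og1, "CG2": cg2})
    return atoms


def _arginine_head(origin: np.ndarray) -> dict[str, np.ndarray]:
    cd = origin
    ne = cd + np.array([1.46, 0.0, 0.0])
    cz = place_atom(cd + np.array([0.0, 1.0, 0.0]), cd, ne, 1.33, 124.0, 180.0)
    nh1 = place_atom(cd, ne, cz, 1.33, 120.0, 0.0)
    nh2 = place_atom(cd, ne, cz, 1.33, 120.0, 180.0)
    return {"CD": cd, "NE": ne, "CZ": cz, "NH1": nh1, "NH2": nh2}


def _glutamine_head(origin: np.ndarray) -> dict[str, np.ndarray]:
    cg = origin
    cd = cg + np.array([1.52, 0.0, 0.0])
    oe1 = place_atom(cg + np.array([0.0, 1.0, 0.0]), cg, cd, 1.23, 121.0, 0.0)
    ne2 = place_atom(cg + np.array([0.0, 1.0, 0.0]), cg, cd, 1.33, 117.0, 180.0)
    return {"CG": cg, "CD": cd, "OE1": oe1, "NE2": ne2}


def _aspartate_head(origin: np.ndarray) -> dict[str, np.ndarray]:
    cb = origin
    cg = cb + np.array([1.52, 0.0, 0.0])
    od1 = place_atom(cb + np.array([0.0, 1.0, 0.0]), cb, cg, 1.25, 118.0, 0.0)
    od2 = place_atom(cb + np.array([0.0, 1.0, 0.0]), cb, cg, 1.25, 118.0, 180.0)
    return {"CB": cb, "CG": cg, "OD1": od1, "OD2": od2}


def _phosphate(origin: np.ndarray) -> dict[str, np.ndarray]:
    p = origin
    op1 = p + 1.48 * _unit(np.array([1.0, 1.0, 0.2]))
    op2 = p + 1.48 * _unit(np.array([-1.0, 1.0, -0.2]))
    o5 = p + 1.60 * _unit(np.array([0.3, -1.0, 0.4]))
    c5 = o5 + 1.44 * _unit(np.array([0.9, -0.8, -0.3]))
    return {"P": p, "OP1": op1, "OP2": op2, "O5'": o5, "C5'": c5}


def _pyrimidine_ring(origin: np.ndarray) -> dict[str, np.ndarray]:
    """Planar cytosine-like ring with exocyclic O2 and N4."""
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    atoms: dict[str, np.ndarray] = {}
    r = 1.38
    for i, name in enumerate(names):
        ang = math.radians(60.0 * i)
        atoms[name] = origin + np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    center = origin
    atoms["O2"] = atoms["C2"] + 1.23 * _unit(atoms["C2"] - center)
    atoms["N4"] = atoms["C4"] + 1.33 * _unit(atoms["C4"] - center)
    return atoms


def _guanine_fragment(origin: np.ndarray) -> dict[str, np.ndarray]:
    """Planar six-ring of guanine with O6/N2 plus an approximate N7/C8."""
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    atoms: dict[str, np.ndarray] = {}
    r = 1.38
    for i, name in enumerate(names):
        ang = math.radians(60.0 * i)
        atoms[name] = origin + np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    atoms["O6"] = atoms["C6"] + 1.23 * _unit(atoms["C6"] - origin)
    atoms["N2"] = atoms["C2"] + 1.33 * _unit(atoms["C2"] - origin)
    mid = 0.5 * (atoms["C4"] + atoms["C5"])
    out = _unit(mid - origin)
    atoms["N7"] = atoms["C5"] + 1.37 * _unit(out + np.array([0.0, 0.45, 0.0]))
    atoms["C8"] = mid + 2.2 * out
    return atoms


def _ribose(origin: np.ndarray) -> dict[str, np.ndarray]:
    """Approximately planar furanose with O2' and O3' on one face."""
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    atoms: dict[str, np.ndarray] = {}
    r = 1.30
    for i, name in enumerate(names):
        ang = math.radians(72.0 * i)
        atoms[name] = origin + np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    atoms["O2'"] = atoms["C2'"] + 1.41 * _unit(
        _unit(atoms["C2'"] - origin) + np.array([0.0, 0.0, 0.9])
    )
    atoms["O3'"] = atoms["C3'"] + 1.42 * _unit(
        _unit(atoms["C3'"] - origin) + np.array([0.0, 0.0, 0.7])
    )
    atoms["C5'"] = atoms["C4'"] + 1.51 * _unit(
        _unit(atoms["C4'"] - origin) + np.array([0.0, 0.0, -0.8])
    )
    return atoms


_ELEMENT_FROM_NAME = lambda name: name[0] if name[0] in "NOPSC" else "C"

_PROTEIN_MOTIFS: list[tuple[str, callable]] = [
    ("SER", _serine),
    ("THR", _threonine),
    ("ARG", _arginine_head),
    ("GLN", _glutamine_head),
    ("ASP", _aspartate_head),
]
_NUCLEIC_MOTIFS: list[tuple[str, callable]] = [
    ("A", _phosphate),
    ("C", _pyrimidine_ring),
    ("A", _ribose),
    ("G", _guanine_fragment),
]


def _make_residue(name: str, seqid: int, coords: dict[str, np.ndarray]) -> Residue:
    residue = Residue(name=name, seqid=seqid)
    for atom_name, pos in coords.items():
        residue.atoms.append(
            Atom(name=atom_name, element=_ELEMENT_FROM_NAME(atom_name), position=pos)
        )
    return residue


def _assemble(entry_id: str, protein: list[Residue], nucleic: list[Residue]) -> Structure:
    structure = Structure(entry_id=entry_id, method="X-RAY DIFFRACTION", resolution=2.0)
    chain_a = Chain(id="A", residues=protein)
    chain_b = Chain(id="B", residues=nucleic)
    from .structure_io import classify_chain

    for chain in (chain_a, chain_b):
        if chain.residues:
            chain.kind = classify_chain(chain)
            structure.chains.append(chain)
    return structure


# ---------------------------------------------------------------------------
# controlled single-pair fixtures
# ---------------------------------------------------------------------------

ACCEPTOR_MOTIFS: dict[str, tuple[str, str, str, float]] = {
    # motif key -> (residue name, acceptor atom, antecedent atom, AA bond length)
    "U:O4": ("U", "O4", "C4", 1.23),
    "DC:O2": ("DC", "O2", "C2", 1.23),
    "DA:OP1": ("DA", "OP1", "P", 1.48),
}


class UnrealizableFixture(ValueError):
    """The requested geometry violates the triangle constraints."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a controlled donor-acceptor pair fixture.

    The donor is the backbone amide of the second glycine of a dipeptide
    (a fixed sp2 hydrogen, so the target angles are realized exactly);
    the acceptor motif is a minimal two-atom fragment from
    :data:`ACCEPTOR_MOTIFS`.
    """

    acceptor_motif: str = "U:O4"
    d_da: float = 2.9
    dha_deg: float = 150.0
    haaa_deg: float = 120.0
    seed: int = 0
    decoy_count: int = 2


def _pair_geometry(spec: FixtureSpec):
    """Donor/H/acceptor/antecedent positions realizing the spec targets."""
    if spec.acceptor_motif not in ACCEPTOR_MOTIFS:
        raise UnrealizableFixture(f"unknown acceptor motif {spec.acceptor_motif!r}")
    res_name, acc_name, ant_name, aa_bond = ACCEPTOR_MOTIFS[spec.acceptor_motif]

    gly1 = _glycine_backbone(np.zeros(3))
    # trans peptide bond to residue 2
    n2 = place_atom(gly1["N"], gly1["CA"], gly1["C"], 1.33, 116.0, 180.0)
    ca2 = place_atom(gly1["CA"], gly1["C"], n2, 1.46, 122.0, 180.0)
    c2 = place_atom(gly1["C"], n2, ca2, 1.52, 110.0, 180.0)
    o2 = place_atom(n2, ca2, c2, 1.23, 121.0, 0.0)
    gly2 = {"N": n2, "CA": ca2, "C": c2, "O": o2}

    # snap the donor frame to the PDB coordinate grid (0.001 Å) before
    # deriving the acceptor geometry, so the targets survive serialization
    gly1 = {k: np.round(v, 3) for k, v in gly1.items()}
    gly2 = {k: np.round(v, 3) for k, v in gly2.items()}

    donor = gly2["N"]
    hydrogen = bisector_hydrogen(donor, gly1["C"], gly2["CA"], BOND_LENGTH["N"])

    # law of cosines: fix d_ha from the targeted D-A distance and D-H-A angle
    d_dh = BOND_LENGTH["N"]
    cos_t = math.cos(math.radians(spec.dha_deg))
    disc = cos_t * cos_t * d_dh * d_dh - d_dh * d_dh + spec.d_da**2
    if disc < 0:
        raise UnrealizableFixture(
            f"d_da={spec.d_da} with DHA={spec.dha_deg} deg is geometrically impossible"
        )
    d_ha = d_dh * cos_t + math.sqrt(disc)
    if d_ha <= 0:
        raise UnrealizableFixture("non-positive H-A distance implied by the targets")

    u1 = _unit(donor - hydrogen)
    # in-plane perpendicular: use the peptide plane normal to stay deterministic
    normal = _unit(np.cross(gly1["C"] - donor, gly2["CA"] - donor))
    perp = _unit(np.cross(normal, u1))
    theta = math.radians(spec.dha_deg)
    acceptor = np.round(hydrogen + d_ha * (math.cos(theta) * u1 + math.sin(theta) * perp), 3)

    u2 = _unit(hydrogen - acceptor)
    perp2 = _unit(np.cross(normal, u2))
    psi = math.radians(spec.haaa_deg)
    antecedent = acceptor + aa_bond * (math.cos(psi) * u2 + math.sin(psi) * perp2)
    return gly1, gly2, res_name, acc_name, ant_name, acceptor, antecedent


def make_pair_fixture(spec: FixtureSpec) -> str:
    """PDB text with one donor-acceptor pair at the spec's exact geometry.

    Decoy residues (uracil O4 fragments) are placed on the nucleic chain
    far beyond the D-A cutoff of every other atom.  Same spec (including
    seed) -> byte-identical text.
    """
    gly1, gly2, res_name, acc_name, ant_name, acceptor, antecedent = _pair_geometry(spec)

    protein = [_make_residue("GLY", 1, gly1), _make_residue("GLY", 2, gly2)]
    nucleic = [_make_residue(res_name, 1, {acc_name: acceptor, ant_name: antecedent})]

    rng = np.random.default_rng(spec.seed)
    for k in range(spec.decoy_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        base = acceptor + (30.0 + 8.0 * k) * direction
        nucleic.append(
            _make_residue("U", 11 + k, {"C4": base, "O4": base + np.array([0.0, 0.0, 1.23])})
        )
    structure = _assemble("FIXT", protein, nucleic)
    return write_pdb(structure)


# ---------------------------------------------------------------------------
# randomized multi-motif fixtures
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_random_fixture(
    seed: int,
    n_protein: int = 8,
    n_nucleic: int = 8,
    box: float = 12.0,
) -> str:
    """PDB text with randomly placed protein and nucleic-acid motifs.

    Motifs are internally rigid idealized fragments; their random poses in
    a ``box``-Å cube generate donor-acceptor contacts spanning all four
    criteria boundaries.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)

    def scatter(motifs, count):
        residues = []
        for i in range(count):
            name, builder = motifs[int(rng.integers(len(motifs)))]
            coords = builder(np.zeros(3))
            rot = _random_rotation(rng)
            offset = rng.uniform(0.0, box, size=3)
            placed = {k: rot @ v + offset for k, v in coords.items()}
            residues.append(_make_residue(name, i + 1, placed))
        return residues

    protein = scatter(_PROTEIN_MOTIFS, n_protein)
    nucleic = scatter(_NUCLEIC_MOTIFS, n_nucleic)
    structure = _assemble("RAND", protein, nucleic)
    return write_pdb(structure)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_hbonds(
    structure: Structure,
    criteria: CriteriaConfig | None = None,
    roles: RoleDictionary | None = None,
) -> list[HBond]:
    """All-pairs hydrogen-bond detection with no spatial index.

    Shares the role dictionary and hydrogen-placement model with the
    engine (they define the method) but discovers pairs by a plain double
    loop and evaluates every criterion with its own arithmetic, so it is
    an independent check of the engine's accelerated search.
    """
    criteria = criteria or CriteriaConfig()
    if not (structure.chains_of_kind("protein") and structure.chains_of_kind("dna", "rna")):
        return []
    donors, acceptors = collect_sites(structure, roles or default_roles())

    def angle_deg(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
        u, v = p - q, r - q
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    bonds: list[HBond] = []
    for donor in donors:
        for acceptor in acceptors:
            if donor.is_protein == acceptor.is_protein:
                continue
            dpos, apos = donor.atom.position, acceptor.atom.position
            d_da = float(np.linalg.norm(dpos - apos))
            if d_da >= criteria.max_da:
                continue
            if not acceptor.antecedents:
                continue
            if donor.entry.rotatable and donor.frame is not None:
                length = BOND_LENGTH.get(donor.atom.element, BOND_LENGTH["N"])
                hydrogens = [
                    rotor_hydrogen_toward(dpos, donor.frame[0], donor.frame[1], apos, length)
                ]
            else:
                hydrogens = [p.position for p in donor.placements]
            best = None
            for hpos in hydrogens:
                d_ha = float(np.linalg.norm(hpos - apos))
                if d_ha >= criteria.max_ha:
                    continue
                if angle_deg(dpos, hpos, apos) <= criteria.min_dha_deg:
                    continue
                if best is None or d_ha < best[1]:
                    best = (hpos, d_ha)
            if best is None:
                continue
            hpos, d_ha = best
            haaa = [
                (angle_deg(hpos, apos, aa_pos), name)
                for name, aa_pos in acceptor.antecedents
            ]
            if any(ang <= criteria.min_haaa_deg for ang, _ in haaa):
                continue
            worst = min(haaa)
            bonds.append(
                HBond(
                    donor=donor.ref,
                    hydrogen=hpos,
                    acceptor=acceptor.ref,
                    antecedent=worst[1],
                    d_ha=d_ha,
                    d_da=d_da,
                    angle_dha=angle_deg(dpos, hpos, apos),
                    angle_haaa=worst[0],
                    donor_is_protein=donor.is_protein,
                )
            )
    bonds.sort(key=HBond.sort_key)
    return bonds


# ---------------------------------------------------------------------------
# worked example: threonine vs cytidine double-hydroxyl motif
# ---------------------------------------------------------------------------

def make_thr_cytidine_example() -> str:
    """Synthetic reconstruction of the Thr224(A) / C8(R) worked example.

    Builds, from idealized geometry, the classic threonine-cytidine
    double-hydroxyl motif reported for PDB entry 4F3T: Thr OG1 donates to
    both O2' and O3' of the cytidine while the cytidine O2' donates back
    to OG1 — three hydrogen bonds between one amino acid and one
    nucleotide.  These are *constructed* coordinates, not the deposited
    ones (the construction is deterministic).  Chain A holds residues
    223-225 with the threonine at author number 224; chain R holds
    nucleotides 7-9 with the cytidine at author number 8.
    """
    ribose = _ribose(np.zeros(3))
    base = _pyrimidine_ring(np.array([2.8, -1.2, -1.5]))
    # attach the base loosely on the opposite face from the hydroxyls
    base = {k: v + np.array([0.0, 0.0, -1.2]) for k, v in base.items()}
    cytidine = {**ribose, **base}

    o2p, o3p = ribose["O2'"], ribose["O3'"]
    c2p, c3p, c1p, c4p, o4p = (
        ribose["C2'"], ribose["C3'"], ribose["C1'"], ribose["C4'"], ribose["O4'"]
    )

    # place OG1: ~2.75 A from O2', within range of O3', on the hydroxyl face,
    # far enough from every other acceptor of the nucleotide
    og1 = None
    others = [ribose["O4'"], base["O2"], base["N3"], base["N4"]]
    for direction in _sphere_directions(2.0):
        cand = o2p + 2.75 * direction
        if not 100.0 <= _angle_deg(c2p, o2p, cand) <= 125.0:
            continue
        d3 = np.linalg.norm(cand - o3p)
        if not 2.7 <= d3 <= 3.4:
            continue
        if _angle_deg(c3p, o3p, cand) <= 105.0:
            continue
        if min(np.linalg.norm(cand - x) for x in others) < 4.2:
            continue
        og1 = cand
        break
    assert og1 is not None

    # the phosphorus of the next nucleotide, bonded to O3' (so O3' is a
    # bridging, acceptor-only oxygen as in the interior of a chain), placed
    # away from the hydroxyl face so the incoming bond clears its antecedent
    p9 = None
    for direction in _sphere_directions(4.0):
        cand = o3p + 1.60 * direction
        if not 110.0 <= _angle_deg(c3p, o3p, cand) <= 128.0:
            continue
        if _angle_deg(cand, o3p, og1) <= 110.0:
            continue
        if np.linalg.norm(cand - o2p) < 2.8 or np.linalg.norm(cand - c2p) < 2.6:
            continue
        if np.linalg.norm(cand - og1) < 3.2:
            continue
        p9 = cand
        break
    assert p9 is not None

    # CB opposite the two acceptors, keeping every approach angle moderate
    cb = None
    for direction in _sphere_directions(2.0):
        cand = og1 + 1.43 * direction
        a2 = _angle_deg(cand, og1, o2p)
        a3 = _angle_deg(cand, og1, o3p)
        if not (105.0 <= a2 <= 145.0 and 105.0 <= a3 <= 145.0):
            continue
        if np.linalg.norm(cand - o2p) < 2.9 or np.linalg.norm(cand - o3p) < 2.9:
            continue
        # the incoming bond O2' -> OG1 must clear its antecedent angle
        h_o2p = rotor_hydrogen_toward(o2p, c2p, c1p, og1, BOND_LENGTH["O"])
        if _angle_deg(h_o2p, og1, cand) <= 100.0:
            continue
        cb = cand
        break
    assert cb is not None

    # build the rest of the threonine pointing away from the nucleotide
    away = _unit(cb - og1)
    ca = cb + 1.53 * _unit(away + 0.4 * np.array([0.0, 0.0, 1.0]))
    cg2 = cb + 1.52 * _unit(away + 0.4 * np.array([0.0, 1.0, 0.0]))
    n = ca + 1.46 * _unit(away + 0.3 * np.array([0.0, 1.0, 0.3]))
    c = ca + 1.52 * _unit(away + 0.3 * np.array([0.0, -1.0, -0.3]))
    o = c + 1.23 * away
    thr = {"N": n, "CA": ca, "CB": cb, "OG1": og1, "CG2": cg2, "C": c, "O": o}
    c223 = n + 1.33 * _unit(away + np.array([0.3, 0.5, 0.0]))

    protein = [
        _make_residue("GLY", 223, {"C": c223}),
        _make_residue("THR", 224, thr),
        _make_residue("GLY", 225, {"CA": ca + 6.0 * away}),
    ]
    nucleic = [
        _make_residue("G", 7, {"C1'": o4p + 6.5 * _unit(o4p - c2p)}),
        _make_residue("C", 8, cytidine),
        _make_residue("C", 9, {"P": p9}),
    ]

    structure = Structure(entry_id="4F3T", method="X-RAY DIFFRACTION", resolution=2.0)
    chain_a = Chain(id="A", residues=protein, kind="protein")
    chain_r = Chain(id="R", residues=nucleic, kind="rna")
    structure.chains = [chain_a, chain_r]
    return write_pdb(structure)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosine = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosine))))
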