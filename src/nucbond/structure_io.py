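"""Reading coordinate files, chain classification and complex selection.

Parsing is delegated to :mod:`gemmi`; on top of it this module applies the
selection policy used throughout the package:

* only the first coordinate model is kept (X-ray entries have one);
* per atom site, only the alternate location with the highest occupancy is
  kept (ties broken toward the lexicographically smallest altloc);
* waters and unmapped hetero residues are dropped (selenomethionine is
  aliased to methionine); file hydrogens are dropped because hydrogen
  positions are always inferred downstream;
* chains are classified as protein / dna / rna / other by majority vote
  over residue names.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi

from .model import (
    AMINO_ACIDS,
    DEOXYRIBONUCLEOTIDES,
    NUCLEOTIDES,
    RIBONUCLEOTIDES,
    Atom,
    Chain,
    Residue,
    Structure,
)

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}

# Modified residues mapped onto their standard parent; atoms renamed where
# the substituted atom takes part in hydrogen bonding.
RESIDUE_ALIASES: dict[str, str] = {"MSE": "MET"}
ATOM_ALIASES: dict[tuple[str, str], str] = {("MSE", "SE"): "SD"}


class StructureParseError(ValueError):
    """The input file could not be parsed in the requested format."""


class EmptyStructureError(StructureParseError):
    """The input file yielded no usable atoms."""


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties to smallest altloc."""
    by_name: dict[str, Atom] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        # Blank altloc sorts before 'A', so an unconformed atom wins ties.
        if prev is None or (-atom.occupancy, atom.altloc) < (-prev.occupancy, prev.altloc):
            by_name[atom.name] = atom
    return list(by_name.values())


def classify_chain(chain: Chain) -> str:
    """Classify a chain by majority residue-name composition.

    Returns ``protein`` if more than half of the residues carry standard
    amino-acid names, ``dna``/``rna`` analogously for nucleotide names, and
    ``other`` when no class reaches a majority.
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.id!r} has no residues")
    n = len(chain.residues)
    counts = {"protein": 0, "dna": 0, "rna": 0}
    for res in chain.residues:
        if res.name in AMINO_ACIDS:
            counts["protein"] += 1
        elif res.name in DEOXYRIBONUCLEOTIDES:
            counts["dna"] += 1
        elif res.name in RIBONUCLEOTIDES:
            counts["rna"] += 1
    for kind, count in counts.items():
        if count * 2 > n:
            return kind
    return "other"


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into the domain model.

    Parameters
    ----------
    path:
        Input coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``None`` to detect from the extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyStructureError(f"{path.name}: empty file")
    fmt = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc

    info = dict(st.info)
    entry_id = info.get("_entry.id") or st.name
    method = info.get("_exptl.method", "")
    resolution = st.resolution if st.resolution > 0 else None

    structure = Structure(entry_id=entry_id, method=method, resolution=resolution)
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no coordinate model")
    if len(st) > 1:
        logger.info("%s: keeping model 1 of %d", entry_id, len(st))
    model = st[0]

    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            name = gres.name.strip()
            if name in WATER_NAMES:
                logger.debug("%s: skipping water %s %s", entry_id, gchain.name, gres.seqid.num)
                continue
            alias_source = name
            name = RESIDUE_ALIASES.get(name, name)
            if name not in AMINO_ACIDS and name not in NUCLEOTIDES:
                logger.info(
                    "%s: skipping unmapped hetero residue %s %s/%s",
                    entry_id, name, gchain.name, gres.seqid.num,
                )
                continue
            icode = gres.seqid.icode.strip()
            residue = Residue(name=name, seqid=gres.seqid.num, icode=icode)
            atoms: list[Atom] = []
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue  # hydrogen positions are inferred, never read
                atom_name = ATOM_ALIASES.get((alias_source, gatom.name), gatom.name)
                altloc = gatom.altloc if gatom.altloc not in ("\x00", " ") else ""
                atoms.append(
                    Atom(
                        name=atom_name,
                        element=gatom.element.name,
                        position=[gatom.pos.x, gatom.pos.y, gatom.pos.z],
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        altloc=altloc,
                    )
                )
            residue.atoms = _resolve_altlocs(atoms)
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            chain.kind = classify_chain(chain)
            structure.chains.append(chain)

    if structure.n_atoms == 0:
        raise EmptyStructureError(f"{path.name}: no atoms after filtering")
    return structure


def select_complex(
    structure: Structure,
    max_resolution: float = 3.0,
    method: str = "X-RAY",
) -> bool:
    """Decide whether a complex enters the data set.

    True iff the experiment is X-ray crystallography, the resolution is
    present and at or better than ``max_resolution`` (the boundary is
    inclusive: "3.0 Å or better" admits 3.0 Å), and the structure contains
    at least one protein chain and at least one DNA or RNA chain.
    """
    if method.upper().replace("-", "") not in structure.method.upper().replace("-", ""):
        logger.info("%s: rejected, method %r", structure.entry_id, structure.method)
        return False
    if structure.resolution is None:
        logger.info("%s: rejected, no resolution record", structure.entry_id)
        return False
    if structure.resolution > max_resolution:
        logger.info(
            "%s: rejected, resolution %.2f Å > %.2f Å",
            structure.entry_id, structure.resolution, max_resolution,
        )
        return False
    has_protein = bool(structure.chains_of_kind("protein"))
    has_nucleic = bool(structure.chains_of_kind("dna", "rna"))
    if not (has_protein and has_nucleic):
        logger.info("%s: rejected, not a protein-nucleic-acid complex", structure.entry_id)
        return False
    return True


def write_pdb(structure: Structure) -> str:
    """Serialize the retained atoms back to PDB-format text.

    Only records the parser itself consumes are written (HEADER, EXPDTA,
    REMARK 2, ATOM, TER, END), which makes parse -> write -> parse an
    identity on the domain model.
    """
    lines: list[str] = []
    entry = (structure.entry_id or "XXXX").upper()[:4]
    lines.append(f"HEADER    NUCBOND COMPLEX                         01-JAN-00   {entry}")
    if structure.method:
        lines.append(f"EXPDTA    {structure.method}")
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB column convention: 1-char elements start in column 14.
                if len(name) < 4 and len(atom.element) == 1:
                    name = f" {name:<3s}"
                else:
                    name = f"{name:<4s}"
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {name}{atom.altloc or ' '}{res.name:>3s} "
                    f"{chain.id:1s}{res.seqid:4d}{res.icode or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} {chain.id:1s}{chain.residues[-1].seqid:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
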