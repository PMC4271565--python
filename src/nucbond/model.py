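"""Hierarchical coordinate model for protein-nucleic-acid complexes.

A deliberately small domain model: a :class:`Structure` holds classified
:class:`Chain` objects, each an ordered list of :class:`Residue` objects
carrying :class:`Atom` coordinates.  Author residue numbering (``resSeq``
plus insertion code) is preserved verbatim because binding sites are
conventionally cited by author numbers (e.g. "Thr224 of chain A").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Three-letter codes of the 20 standard amino acids.
AMINO_ACIDS: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)
DEOXYRIBONUCLEOTIDES: frozenset[str] = frozenset({"DA", "DC", "DG", "DT"})
RIBONUCLEOTIDES: frozenset[str] = frozenset({"A", "C", "G", "U"})
NUCLEOTIDES: frozenset[str] = DEOXYRIBONUCLEOTIDES | RIBONUCLEOTIDES

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
NT_TO_ONE = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "U": "U",
}


@dataclass
class Atom:
    """A heavy atom (or an inferred hydrogen) with Cartesian coordinates in Å."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    inferred_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue identified by name and author numbering (resSeq + insertion code)."""

    name: str
    seqid: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def author_id(self) -> str:
        return f"{self.seqid}{self.icode}".strip()

    def find_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.name} {self.author_id} ({len(self.atoms)} atoms)>"


@dataclass
class Chain:
    """An ordered run of residues; ``kind`` is one of protein/dna/rna/other."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    kind: str = "other"

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """One coordinate model of an experimentally determined complex."""

    entry_id: str
    method: str = ""
    resolution: float | None = None
    chains: list[Chain] = field(default_factory=list)

    def get_chain(self, chain_id: str) -> Chain | None:
        for chain in self.chains:
            if chain.id == chain_id:
                return chain
        return None

    def chains_of_kind(self, *kinds: str) -> list[Chain]:
        return [c for c in self.chains if c.kind in kinds]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


@dataclass(frozen=True, order=True)
class AtomRef:
    """A hashable, sortable reference to one atom site in a structure."""

    chain_id: str
    seqid: int
    icode: str
    res_name: str
    atom_name: str

    @classmethod
    def of(cls, chain: Chain, residue: Residue, atom: Atom) -> "AtomRef":
        return cls(chain.id, residue.seqid, residue.icode, residue.name, atom.name)

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqid, self.icode)
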