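"""Donor/acceptor role dictionary for standard residues.

Which atoms can donate or accept hydrogen bonds — and through which frame
and antecedent atoms the hydrogen geometry is evaluated — is an inventory,
not an algorithm.  It is shipped as a human-readable TSV
(``data/roles.tsv``) so it can be inspected, versioned and overridden.

Conventions encoded here:

* carbon never donates (no C-H...O interactions);
* amide/guanidinium/amino nitrogens are pure donors, carbonyl and
  carboxylate oxygens and phosphate oxygens pure acceptors;
* hydroxyls (Ser OG, Thr OG1, Tyr OH, ribose O2', terminal O3'/O5'),
  sulfhydryl Cys SG and His ring nitrogens are both donor and acceptor;
* ring nitrogens of the nucleobases that are occasionally observed in a
  protonated (donating) form — adenine N1/N3, cytosine N3, guanine N1/N3,
  uracil/thymine N3 — carry both roles;
* backbone O3'/O5' donate only at a chain terminus, where they are
  hydroxyls rather than phosphodiester bridges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import AMINO_ACIDS, NUCLEOTIDES, RIBONUCLEOTIDES

logger = logging.getLogger(__name__)

_GROUPS: dict[str, frozenset[str]] = {
    "@protein": AMINO_ACIDS,
    "@protein!PRO": AMINO_ACIDS - {"PRO"},
    "@nt": NUCLEOTIDES,
    "@ribo": RIBONUCLEOTIDES,
}


@dataclass(frozen=True)
class RoleEntry:
    """Hydrogen-bonding role of one atom type within one residue type."""

    residue_name: str
    atom_name: str
    donor: bool
    acceptor: bool
    antecedents: tuple[str, ...] = ()
    rotatable: bool = False
    donor_geometry: str = ""          # bisector | amide2 | rotor | rotor3
    frame: tuple[str, ...] = ()       # atoms defining the hydrogen frame
    donor_terminal_only: bool = False

    def __post_init__(self) -> None:
        if not (self.donor or self.acceptor):
            raise ValueError(f"{self.residue_name}/{self.atom_name}: neither donor nor acceptor")
        if self.acceptor and not self.antecedents:
            raise ValueError(f"{self.residue_name}/{self.atom_name}: acceptor without antecedents")


@dataclass
class RoleDictionary:
    """Lookup table of :class:`RoleEntry` keyed by (residue name, atom name)."""

    entries: dict[tuple[str, str], RoleEntry] = field(default_factory=dict)
    _warned: set[str] = field(default_factory=set, repr=False)

    def lookup(self, residue_name: str, atom_name: str) -> RoleEntry | None:
        """Return the role of an atom, or None if it has no H-bonding role."""
        entry = self.entries.get((residue_name, atom_name))
        if entry is None and residue_name not in self._known_residues:
            if residue_name not in self._warned:
                logger.info("no roles defined for residue %r", residue_name)
                self._warned.add(residue_name)
        return entry

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    @property
    def _known_residues(self) -> set[str]:
        return {res for res, _ in self.entries}


def _parse_fields(raw: str) -> tuple[str, ...]:
    return tuple(t for t in raw.split(",") if t and t != "-") if raw != "-" else ()


def load_roles(path: str | Path | None = None) -> RoleDictionary:
    """Load the role dictionary, from ``path`` or the packaged default TSV."""
    if path is None:
        text = resources.files("nucbond.data").joinpath("roles.tsv").read_text()
    else:
        text = Path(path).read_text()

    rd = RoleDictionary()
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        residues_token = row["residue"]
        if residues_token in _GROUPS:
            residues = sorted(_GROUPS[residues_token])
        else:
            residues = residues_token.split(",")
        for res in residues:
            entry = RoleEntry(
                residue_name=res,
                atom_name=row["atom"],
                donor=row["donor"] == "1",
                acceptor=row["acceptor"] == "1",
                antecedents=_parse_fields(row["antecedents"]),
                rotatable=row["rotatable"] == "1",
                donor_geometry=row["donor_geometry"] if row["donor_geometry"] != "-" else "",
                frame=_parse_fields(row["frame"]),
                donor_terminal_only=row["terminal_only"] == "1",
            )
            key = (res, entry.atom_name)
            if key in rd.entries:
                raise ValueError(f"duplicate role row for {key} at line {lineno}")
            rd.entries[key] = entry
    return rd


_default: RoleDictionary | None = None


def default_roles() -> RoleDictionary:
    """The packaged role dictionary (cached)."""
    global _default
    if _default is None:
        _default = load_roles()
    return _default
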