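"""Residue-level binding annotation and XML/TSV serialization.

A residue is a *binding site* when it participates in at least one
interface hydrogen bond; per chain the annotation carries the one-letter
sequence and an equally long binding string over ``{'+', '-'}``.  Only
residues with resolved coordinates are indexed, and an index map from
string position to author residue number is emitted alongside, so that
binding sites can be cited by author numbering.

The XML rendering has one ``BindPartner`` element per complex (PDB id,
per-chain sequence/binding/index elements) and one ``BindingSite``
element per hydrogen bond with donor/acceptor chain, author index,
residue and atom attributes.  A formal XSD is shipped in
``data/bindpartner.xsd`` and the writer's output validates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .engine import HBond
from .model import AA_THREE_TO_ONE, NT_TO_ONE, AtomRef, Structure

_SEQ_TAG = {"protein": "proSeq", "dna": "dnaSeq", "rna": "rnaSeq"}
_BND_TAG = {"protein": "proBnd", "dna": "dnaBnd", "rna": "rnaBnd"}
_IDX_TAG = {"protein": "proIdx", "dna": "dnaIdx", "rna": "rnaIdx"}
_TAG_KIND = {v: k for k, v in _SEQ_TAG.items()}


@dataclass
class ChainAnnotation:
    """Sequence, binding string and author-number index map of one chain."""

    chain_id: str
    kind: str                      # protein | dna | rna
    sequence: str
    binding: str
    author_ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.binding) == len(self.author_ids)):
            raise ValueError(
                f"chain {self.chain_id}: sequence, binding string and index map "
                "must have equal length"
            )


@dataclass
class BindingAnnotation:
    """Binding sites of one complex, from atomic pairs up to binding strings."""

    entry_id: str
    chains: list[ChainAnnotation] = field(default_factory=list)
    hbonds: list[HBond] = field(default_factory=list)

    @property
    def residue_pairs(self) -> list[tuple[tuple[str, str], tuple[str, str]]]:
        """Unique (protein residue, nucleotide) pairs as (chain, author id)."""
        pairs = []
        seen = set()
        for bond in self.hbonds:
            prot = bond.donor if bond.donor_is_protein else bond.acceptor
            nuc = bond.acceptor if bond.donor_is_protein else bond.donor
            pair = (
                (prot.chain_id, f"{prot.seqid}{prot.icode}"),
                (nuc.chain_id, f"{nuc.seqid}{nuc.icode}"),
            )
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
        return pairs

    def chain(self, chain_id: str) -> ChainAnnotation:
        for ca in self.chains:
            if ca.chain_id == chain_id:
                return ca
        raise KeyError(chain_id)


def _one_letter(kind: str, name: str) -> str:
    table = AA_THREE_TO_ONE if kind == "protein" else NT_TO_ONE
    return table.get(name, "X")


def residue_binding_map(hbonds: list[HBond], structure: Structure) -> BindingAnnotation:
    """Project atomic hydrogen bonds onto per-chain binding strings.

    A residue engaged in several bonds is still a single ``'+'``.  A bond
    referencing a residue absent from the structure is a consistency error.
    """
    binding_residues: set[tuple[str, int, str]] = set()
    for bond in hbonds:
        for ref in (bond.donor, bond.acceptor):
            chain = structure.get_chain(ref.chain_id)
            found = chain is not None and any(
                r.seqid == ref.seqid and r.icode == ref.icode for r in chain.residues
            )
            if not found:
                raise ValueError(
                    f"H-bond references residue {ref.chain_id}/{ref.seqid}{ref.icode} "
                    "absent from the structure"
                )
            binding_residues.add(ref.residue_key())

    annotation = BindingAnnotation(entry_id=structure.entry_id, hbonds=list(hbonds))
    for chain in structure.chains:
        if chain.kind not in _SEQ_TAG:
            continue
        seq, bnd, ids = [], [], []
        for res in chain.residues:
            seq.append(_one_letter(chain.kind, res.name))
            key = (chain.id, res.seqid, res.icode)
            bnd.append("+" if key in binding_residues else "-")
            ids.append(res.author_id)
        annotation.chains.append(
            ChainAnnotation(chain.id, chain.kind, "".join(seq), "".join(bnd), ids)
        )
    return annotation


def write_xml(annotation: BindingAnnotation) -> bytes:
    """Serialize an annotation to UTF-8 XML (schema: data/bindpartner.xsd)."""
    root = etree.Element("BindPartner", PDBID=annotation.entry_id)
    for ca in annotation.chains:
        for tag, text in (
            (_SEQ_TAG[ca.kind], ca.sequence),
            (_BND_TAG[ca.kind], ca.binding),
            (_IDX_TAG[ca.kind], " ".join(ca.author_ids)),
        ):
            el = etree.SubElement(root, tag, chain=ca.chain_id)
            el.text = text
    for bond in annotation.hbonds:
        etree.SubElement(
            root,
            "BindingSite",
            PDBID=annotation.entry_id,
            Donor=bond.donor.atom_name,
            DonorChain=bond.donor.chain_id,
            DonorIndex=f"{bond.donor.seqid}{bond.donor.icode}",
            DonorResidue=bond.donor.res_name,
            Acceptor=bond.acceptor.atom_name,
            AcceptorChain=bond.acceptor.chain_id,
            AcceptorIndex=f"{bond.acceptor.seqid}{bond.acceptor.icode}",
            AcceptorResidue=bond.acceptor.res_name,
        )
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _split_author_id(author_id: str) -> tuple[int, str]:
    digits = ""
    i = 0
    if author_id.startswith("-"):
        digits, i = "-", 1
    while i < len(author_id) and author_id[i].isdigit():
        digits += author_id[i]
        i += 1
    return int(digits), author_id[i:]


def read_xml(data: bytes | str | Path) -> BindingAnnotation:
    """Parse a document written by :func:`write_xml` back into an annotation.

    Round-trips sequences, binding strings, index maps and the identity
    fields of every hydrogen bond (geometry is not serialized).
    """
    if isinstance(data, Path):
        root = etree.parse(str(data)).getroot()
    else:
        if isinstance(data, str):
            data = data.encode()
        root = etree.fromstring(data)
    annotation = BindingAnnotation(entry_id=root.get("PDBID"))
    partial: dict[tuple[str, str], dict[str, str]] = {}
    for el in root:
        if el.tag == "BindingSite":
            dnum, dic = _split_author_id(el.get("DonorIndex"))
            anum, aic = _split_author_id(el.get("AcceptorIndex"))
            donor = AtomRef(el.get("DonorChain"), dnum, dic, el.get("DonorResidue"), el.get("Donor"))
            acceptor = AtomRef(
                el.get("AcceptorChain"), anum, aic, el.get("AcceptorResidue"), el.get("Acceptor")
            )
            donor_res = donor.res_name
            annotation.hbonds.append(
                HBond(
                    donor=donor,
                    hydrogen=np.full(3, np.nan),
                    acceptor=acceptor,
                    antecedent="",
                    d_ha=float("nan"),
                    d_da=float("nan"),
                    angle_dha=float("nan"),
                    angle_haaa=float("nan"),
                    donor_is_protein=donor_res in AA_THREE_TO_ONE,
                )
            )
        else:
            base = el.tag[:3]
            kind = _TAG_KIND.get(base + "Seq", None)
            if kind is None:
                continue
            record = partial.setdefault((el.get("chain"), kind), {})
            record[el.tag[3:]] = el.text or ""
    for (chain_id, kind), record in partial.items():
        annotation.chains.append(
            ChainAnnotation(
                chain_id,
                kind,
                record.get("Seq", ""),
                record.get("Bnd", ""),
                record.get("Idx", "").split() if record.get("Idx") else [],
            )
        )
    return annotation


def schema() -> etree.XMLSchema:
    """The shipped XSD as a compiled validator."""
    from importlib import resources

    with resources.files("nucbond.data").joinpath("bindpartner.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def hbonds_to_frame(hbonds: list[HBond]) -> pd.DataFrame:
    """Flat table of atomic pairs, one row per hydrogen bond."""
    rows = []
    for b in hbonds:
        rows.append(
            {
                "donor_chain": b.donor.chain_id,
                "donor_index": f"{b.donor.seqid}{b.donor.icode}",
                "donor_residue": b.donor.res_name,
                "donor_atom": b.donor.atom_name,
                "acceptor_chain": b.acceptor.chain_id,
                "acceptor_index": f"{b.acceptor.seqid}{b.acceptor.icode}",
                "acceptor_residue": b.acceptor.res_name,
                "acceptor_atom": b.acceptor.atom_name,
                "antecedent": b.antecedent,
                "d_ha": round(b.d_ha, 3),
                "d_da": round(b.d_da, 3),
                "angle_dha": round(b.angle_dha, 1),
                "angle_haaa": round(b.angle_haaa, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "donor_chain", "donor_index", "donor_residue", "donor_atom",
            "acceptor_chain", "acceptor_index", "acceptor_residue", "acceptor_atom",
            "antecedent", "d_ha", "d_da", "angle_dha", "angle_haaa",
        ],
    )
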