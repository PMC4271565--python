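"""Amino-acid binding propensity over a corpus of annotated complexes.

With every amino-acid residue in the retained complexes counted once, and
"binding" meaning participation in at least one interface hydrogen bond:

* ``P(+)``  — probability that a residue is a binding site,
* ``P(-) = 1 - P(+)``,
* ``P(A|+)`` — probability that a binding residue is amino acid A,
* ``P(A|-)`` — probability that a non-binding residue is A,
* ``llr(A) = log2( P(A|+) / P(A|-) )`` — positive when A is enriched at
  interfaces, undefined (flagged) when either conditional is zero.

By default the denominator population is *all* amino-acid residues of the
retained complexes, including protein chains that never touch the nucleic
acid; restrict to annotations of interface chains upstream if desired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotation import BindingAnnotation
from .model import AA_THREE_TO_ONE

AA_ORDER = sorted(AA_THREE_TO_ONE)  # alphabetical three-letter codes
_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}


def tally(annotations: Iterable[BindingAnnotation]) -> dict[str, tuple[int, int]]:
    """Per-amino-acid ``(n_binding, n_total)`` counts over a corpus.

    Each residue position counts once; it is binding iff its character in
    the chain's binding string is ``'+'``.
    """
    counts = {aa: [0, 0] for aa in AA_ORDER}
    for annotation in annotations:
        for chain in annotation.chains:
            if chain.kind != "protein":
                continue
            for letter, mark in zip(chain.sequence, chain.binding):
                aa = _ONE_TO_THREE.get(letter)
                if aa is None:
                    continue  # nonstandard residue, outside the 20-letter inventory
                counts[aa][1] += 1
                if mark == "+":
                    counts[aa][0] += 1
    return {aa: (b, t) for aa, (b, t) in counts.items()}


@dataclass
class PropensityTable:
    """Binding propensity statistics; ``table`` has one row per amino acid."""

    table: pd.DataFrame
    p_plus: float
    p_minus: float

    def llr(self, amino_acid: str) -> float:
        """log2 propensity ratio of one amino acid (NaN when undefined)."""
        return float(self.table.loc[amino_acid, "llr"])


def propensity_table(counts: dict[str, tuple[int, int]]) -> PropensityTable:
    """Turn per-amino-acid counts into probabilities and log2 ratios."""
    n_total = sum(t for _, t in counts.values())
    if n_total == 0:
        raise ValueError("empty corpus: no amino-acid residues to tally")
    n_binding = sum(b for b, _ in counts.values())
    n_nonbinding = n_total - n_binding
    p_plus = n_binding / n_total
    p_minus = 1.0 - p_plus

    rows = []
    for aa in AA_ORDER:
        b, t = counts.get(aa, (0, 0))
        nb = t - b
        p_a_plus = b / n_binding if n_binding else math.nan
        p_a_minus = nb / n_nonbinding if n_nonbinding else math.nan
        defined = (
            n_binding > 0 and n_nonbinding > 0 and p_a_plus > 0.0 and p_a_minus > 0.0
        )
        llr = math.log2(p_a_plus / p_a_minus) if defined else math.nan
        rows.append(
            {
                "amino_acid": aa,
                "n_total": t,
                "n_binding": b,
                "p_a_given_plus": p_a_plus,
                "p_a_given_minus": p_a_minus,
                "llr": llr,
                "llr_defined": defined,
            }
        )
    table = pd.DataFrame(rows).set_index("amino_acid")
    return PropensityTable(table=table, p_plus=p_plus, p_minus=p_minus)


def propensity_tsv(result: PropensityTable) -> str:
    """Render the table as TSV, one row per amino acid, alphabetical."""
    df = result.table.reset_index()
    header = f"# P(+) = {result.p_plus:.6g}\tP(-) = {result.p_minus:.6g}\n"
    return header + df.to_csv(sep="\t", index=False, float_format="%.6g")
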