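# nucbond

Hydrogen-bond detection and binding-site annotation at protein–nucleic-acid
interfaces.

Protein–DNA and protein–RNA recognition — transcription factors on their
operators, ribosomal proteins on rRNA, aminoacyl-tRNA synthetases on tRNA —
is mediated to a large extent by hydrogen bonds across the interface.
Crystal structures record heavy-atom coordinates but not the bonds
themselves, and not the hydrogens: at typical resolutions hydrogen atoms
are invisible to X-ray diffraction. `nucbond` is for structural
bioinformaticians who want those interface hydrogen bonds made explicit:
it reads a coordinate file, infers hydrogen positions from the surrounding
heavy atoms, applies four geometric criteria, and reports every
protein↔nucleic-acid bond from the atomic level (donor atom → acceptor
atom) up to residue-level binding strings, with an XML export and corpus
propensity statistics on top.

## Method

A donor–hydrogen…acceptor contact is accepted as a hydrogen bond when all
four criteria hold (strict inequalities, all configurable):

1. d(H···A) < 2.5 Å
2. ∠(D–H···A) > 90°
3. d(D···A) < 3.9 Å
4. ∠(H···A–AA) > 90° for every acceptor antecedent AA present

where D is the donor heavy atom, A the acceptor, and AA a heavy atom
covalently bonded to A. Donor/acceptor roles per (residue, atom) are a
curated inventory shipped as a TSV (`src/nucbond/data/roles.tsv`): amide,
guanidinium and nucleobase amino nitrogens donate; carbonyl, carboxylate
and phosphate oxygens accept; hydroxyls, sulfhydryls, histidine ring
nitrogens and several nucleobase ring nitrogens do both. Hydrogens are
placed at idealized covalent geometry (N–H 1.00 Å, O–H 0.96 Å, S–H 1.34 Å):
sp² donors get fixed in-plane positions, while rotatable donors (Ser/Thr/Tyr
hydroxyls, Cys SH, Lys NH₃⁺, ribose O2′, terminal O3′/O5′) are resolved per
candidate acceptor to the most favorable rotamer on the tetrahedral cone.
Only inter-molecular bonds count (one side protein, the other DNA/RNA);
a complex with no interface bond is eliminated from corpus statistics.

A residue with ≥1 interface bond is a *binding site* ('+', else '−').
Over a corpus, per amino acid A:

    P(+)   = binding residues / all residues
    P(A|+) = binding residues of type A / binding residues
    P(A|−) = non-binding residues of type A / non-binding residues
    llr(A) = log2( P(A|+) / P(A|−) )

Positive llr: enriched at interfaces (arginine, classically); undefined
values (zero numerator or denominator) are flagged rather than fudged.

## Worked example

The repository's worked example is a deterministic synthetic
reconstruction of a documented threonine–cytidine motif (Thr224 of chain A
against nucleotide C8 of chain R in PDB entry 4F3T), in which one
threonine hydroxyl and the ribose 2′/3′ oxygens exchange three hydrogen
bonds:

```sh
python examples/detect_hbonds.py
```

prints

```
structure 4F3T: chain A (protein, 3 residues), chain R (rna, 3 residues)
3 interface hydrogen bonds:
  THR224(A)/OG1  -> C8(R)/O2'   H-A 2.04 A | D-A 2.75 A | D-H-A 129.0 deg | H-A-AA 123.3 deg
  THR224(A)/OG1  -> C8(R)/O3'   H-A 2.49 A | D-A 3.25 A | D-H-A 135.9 deg | H-A-AA 103.2 deg
  C8(R)/O2'  -> THR224(A)/OG1   H-A 1.83 A | D-A 2.75 A | D-H-A 158.8 deg | H-A-AA 144.7 deg
```

Each line is one donor→acceptor bond with its measured geometry: the
threonine OG1 donates to both ribose hydroxyl oxygens and accepts one bond
back from O2′. `examples/annotate_binding_sites.py` shows the same complex
as residue-level binding strings and the XML document;
`examples/propensity_survey.py` runs the corpus statistics over synthetic
complexes; `examples/controlled_fixtures.py` demonstrates the criteria on
fixtures with dialed-in geometry.

The same pipeline is available as a command-line tool:

```sh
nucbond detect input1.pdb input2.pdb --out results/   # XML + TSV per complex
nucbond propensity corpus/*.pdb --out propensity.tsv
nucbond fixture --kind pair --out pair.pdb
```

## Layout

- `src/nucbond/structure_io.py` — PDB/mmCIF parsing (via gemmi), altloc and
  hetero-residue policy, chain classification, complex selection filter
- `src/nucbond/roles.py` + `data/roles.tsv` — donor/acceptor role dictionary
- `src/nucbond/protonation.py` — idealized hydrogen placement
- `src/nucbond/engine.py` — four-criteria detection (KD-tree candidate search)
- `src/nucbond/annotation.py` — binding strings, XML (+ shipped XSD), TSV
- `src/nucbond/propensity.py` — corpus statistics
- `src/nucbond/fixtures.py` — synthetic structures and the brute-force oracle
- `src/nucbond/cli.py` — `nucbond` command
- `docs/methods.md` — model, parameters, numerical choices, limitations
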