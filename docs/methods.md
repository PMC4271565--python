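# Methods

## Model

`nucbond` identifies hydrogen bonds between protein chains and DNA/RNA
chains of an experimentally determined complex. A bond is a geometric
event, not an energetic one: a donor heavy atom D carrying a (modeled)
hydrogen H, an acceptor heavy atom A, and A's covalently bonded
antecedent(s) AA must jointly satisfy

1. d(H···A) < `max_ha` (default 2.5 Å),
2. ∠(D–H···A) > `min_dha` (default 90°),
3. d(D···A) < `max_da` (default 3.9 Å),
4. ∠(H···A–AA) > `min_haaa` (default 90°), for **every** antecedent
   present in the model.

All four inequalities are strict; geometry exactly at a threshold is
rejected. These are the common distance/angle criteria for hydrogen bonds
in crystal structures; they are deliberately permissive about chemistry
(no energy term, no occupancy weighting) and deliberately strict about
geometry. Only inter-molecular bonds are reported — donor and acceptor
must lie in chains of different molecule types (protein vs DNA/RNA) —
and water never mediates: bridged contacts are out of scope, as are
C–H···O interactions, salt-bridge/stacking analyses and any
distance-only (e.g. 5 Å heavy-atom) binding-site definition.

Whether an atom may donate or accept, through which frame its hydrogen is
built, and which antecedents enter criterion 4 is data, not code: the
role dictionary (`data/roles.tsv`) lists every standard amino acid and
(deoxy)ribonucleotide atom with a role. Points worth calling out:

- His ND1/NE2, Ser OG, Thr OG1, Tyr OH, Cys SG and ribose O2′ are both
  donor and acceptor; no tautomer or protonation-state assignment is
  attempted beyond allowing both His nitrogens to act either way.
- Nucleobase ring nitrogens that are occasionally observed protonated
  (adenine N1/N3, cytosine N3, guanine N1/N3, uracil/thymine N3) carry
  both roles; their donor form is rare in real corpora but admissible.
- Backbone O3′/O5′ donate only at a chain terminus, where they are true
  hydroxyls; in mid-chain they are phosphodiester bridges and only accept.
  Terminality is decided from the coordinates (a phosphorus within 2.0 Å
  bonds the oxygen), not from residue numbering.
- O3′ has two antecedents when a next-residue phosphorus is bonded
  (C3′ and that P); criterion 4 then must hold for both. Enforcing the
  angle over *all* present antecedents is the conservative reading;
  acceptors whose antecedents are entirely missing from the model are
  rejected and logged rather than waved through.

## Hydrogen placement

Hydrogens present in the input are discarded; every donor hydrogen is
rebuilt from heavy atoms with textbook covalent geometry: bond lengths
N–H 1.00 Å, O–H 0.96 Å, S–H 1.34 Å; sp² positions in the heavy-atom
plane; sp³ positions on the tetrahedral cone (109.47°).

- backbone amide N (non-proline, non-N-terminal): one H on the external
  bisector of C(prev)–N–CA, requiring an actual peptide bond
  (d(C,N) < 2.0 Å) so chain breaks do not fabricate donors;
- ring N–H (His, Trp, guanine N1, uracil N3, …): external bisector of the
  two ring neighbors;
- NH₂ groups (Arg NH1/NH2, Asn/Gln amides, nucleobase amino groups): two
  in-plane hydrogens at 120° from the N–C bond;
- rotors (Ser OG, Thr OG1, Tyr OH, Cys SG, Lys NZ, ribose O2′, terminal
  O3′/O5′): the torsion is undetermined by heavy atoms, so the hydrogen is
  chosen **per candidate acceptor** as the cone point minimizing the
  H···A distance (closed form: the acceptor's azimuth about the rotor
  axis). This "most favorable rotamer" policy treats an unknown hydroxyl
  torsion permissively, which avoids false negatives for the abundant
  hydroxyl-mediated bonds at protein–RNA interfaces at the cost of
  accepting a bond whenever *some* rotamer would form it. An acceptor
  exactly on the rotor axis (every rotamer equidistant) resolves to the
  canonical anti rotamer, torsion 180° from the reference frame atom.
  Tyr OH is treated as a rotor even though phenol hydrogens prefer the
  ring plane; the in-plane positions are on the cone, so this only widens
  the rotamer search. Lys NZ is a three-hydrogen rotor, but only the
  optimal cone point can ever be the bonding hydrogen, so one suffices.

Donors whose frame atoms are missing get no hydrogen and are logged;
gaps never abort a run. When several hydrogens of one donor qualify
against one acceptor, the smallest d(H···A) is recorded, and at most one
bond is reported per (donor atom, acceptor atom) pair — bifurcated
hydrogens are not double-counted, while one atom may still bond several
partners (the worked example's OG1 does).

## Structure input policy

Parsing stands on gemmi. Policy applied on top, chosen where the method
itself is silent: first coordinate model only; per atom site the highest-
occupancy altloc (ties to the alphabetically smallest indicator); waters
and unmapped hetero residues dropped; MSE aliased to MET (SE→SD);
file hydrogens dropped. Chains are classified by majority residue-name
vote (protein / dna / rna / other, >50% required). The corpus selection
filter keeps X-ray entries with resolution ≤ 3.0 Å — "3.0 Å or better"
is boundary-inclusive — that contain both a protein and a nucleic-acid
chain; structures without any interface bond are then eliminated.
Author residue numbering (resSeq + insertion code) is preserved verbatim
and used in all outputs; binding strings index only residues with
coordinates, with an explicit position→author-number map emitted
alongside rather than gap characters.

## Detection and the independent oracle

Candidate pairs come from a KD-tree radius query at `max_da` over
acceptor coordinates, with the strict inequality and the cross-molecule
restriction applied on top, so the candidate set equals an all-pairs scan
exactly. `brute_force_hbonds` is the package's own check on that claim:
it shares the role dictionary and hydrogen model (they *are* the method)
but discovers pairs with a plain double loop and evaluates the criteria
with independent arithmetic. The test suite and the acceptance script
require exact agreement (bond identities; geometry to 1e-9) over 100
seeded random fixtures. Output ordering is the lexicographic donor/
acceptor key, making every run deterministic.

## Propensity statistics

With each residue counted once and "binding" = at least one interface
bond: P(+) = Σ n_binding / Σ n_total, P(−) = 1 − P(+),
P(A|+) = n_binding(A)/Σ n_binding, P(A|−) = (n_total(A) −
n_binding(A)) / Σ(n_total − n_binding), llr(A) = log2 of their ratio.
The P(A|−) denominator is the non-binding population — the only form
under which Σ_A P(A|−) = 1. The denominator population is all amino-acid
residues of the retained complexes, including protein chains that never
touch the nucleic acid; callers wanting interface-chains-only can filter
the annotations they feed in. No sequence-redundancy reduction is
applied. llr is flagged undefined (NaN) whenever either conditional
probability is zero — degenerate corpora are reported, not smoothed.

## Synthetic fixtures

The generator exists so that every stage is testable from bytes on disk
without downloads; fixtures are written as PDB text and go through the
real parser.

- *Pair fixtures* realize exact target geometry. The donor is a backbone
  amide (fixed hydrogen), so d(H···A) follows from the targeted D···A
  distance and D–H···A angle by the law of cosines; the acceptor and its
  antecedent are then placed in the peptide plane. Coordinates of the
  donor frame are snapped to the PDB 0.001 Å grid *before* the acceptor
  is derived, so the targets survive serialization to within 1e-3 Å
  (angles to ~0.05°). Decoy residues are placed ≥ 30 Å away. Unrealizable
  targets (law-of-cosines discriminant < 0, or a non-positive implied
  distance) raise an error.
- *Random fixtures* scatter small idealized motifs (Ser/Thr/Arg/Gln/Asp
  fragments; phosphate, ribose, cytosine and guanine fragments) with
  seeded uniform rotations and translations in a 12 Å box — dense enough
  that a typical fixture carries a handful of bonds and many near-misses
  around every threshold. Motif geometry is idealized, not
  stereochemically exact: ring puckers are flattened and no attempt is
  made at realistic backbone continuity. Consequently these fixtures
  exercise the geometry engine fully but say nothing about detection
  rates on real structures.
- The *worked example* is a deterministic synthetic reconstruction of the
  threonine–cytidine double-hydroxyl motif (Thr224 chain A / C8 chain R
  of PDB entry 4F3T): constructed coordinates, not the deposited ones.
  It is built by constraint scans over deterministic direction grids so
  that exactly the three documented bonds (OG1→O2′, OG1→O3′, O2′→OG1)
  and no others are geometrically admissible.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100 random fixtures of ~16
motifs (~100 atoms) each, 20 random isometries for the invariance check,
and a 10-residue hand-evaluated propensity corpus — sizes chosen so the
whole validation runs in seconds while covering every code path several
times over. Tolerances: hydrogen bond lengths are exact to 1e-6 Å by
construction; engine-vs-oracle geometry agreement is required to 1e-9;
rigid-motion drift allowed up to 1e-6 (float accumulation under
rotation); fixture round-trip 1e-3 Å (coordinate grid). Angle cosines are
clipped to [−1, 1] before acos. Occupancies outside [0, 1] are clamped at
parse time.

## Known limitations

- Hydrogen placement is idealized; no energy minimization, no pKa or
  tautomer prediction. Against tools that optimize hydrogen-bond networks
  globally, per-acceptor rotamer optimization can differ near the
  criteria boundaries (the worked example's OG1→O3′ bond sits at
  d(H···A) = 2.49 Å — placements a few hundredths of an Å different
  would drop it).
- Modified residues other than MSE are skipped entirely rather than
  mapped to parents.
- Multi-model (NMR-style) inputs use model 1 only; symmetry mates and
  biological assemblies are not expanded, so interfaces formed by
  crystallographic symmetry are invisible.
- The propensity module reports raw corpus frequencies; it applies no
  redundancy reduction, so over-represented families dominate exactly as
  they do in the source data.
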