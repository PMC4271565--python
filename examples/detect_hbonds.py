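"""Detect hydrogen bonds in the threonine-cytidine worked example.

Builds the synthetic reconstruction of the Thr224/C8 binding motif,
runs the four-criteria detection, and prints one line per hydrogen bond.
"""

import tempfile
from pathlib import Path

from nucbond import detect_interface_hbonds, make_thr_cytidine_example, read_structure

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "worked_example.pdb"
    path.write_text(make_thr_cytidine_example())
    structure = read_structure(path)

print(f"structure {structure.entry_id}: "
      + ", ".join(f"chain {c.id} ({c.kind}, {len(c)} residues)" for c in structure.chains))

bonds = detect_interface_hbonds(structure)
print(f"{len(bonds)} interface hydrogen bonds:")
for b in bonds:
    print(
        f"  {b.donor.res_name}{b.donor.seqid}({b.donor.chain_id})/{b.donor.atom_name:4s}"
        f" -> {b.acceptor.res_name}{b.acceptor.seqid}({b.acceptor.chain_id})/{b.acceptor.atom_name:4s}"
        f"  H-A {b.d_ha:.2f} A | D-A {b.d_da:.2f} A | D-H-A {b.angle_dha:5.1f} deg"
        f" | H-A-AA {b.angle_haaa:5.1f} deg"
    )

# Each line is one donor->acceptor bond passing all four criteria
# (H-A < 2.5 A, D-H-A > 90 deg, D-A < 3.9 A, H-A-AA > 90 deg).
# The threonine hydroxyl OG1 donates to both ribose oxygens and accepts
# one bond back from O2' -- the double-hydroxyl motif this example encodes.
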