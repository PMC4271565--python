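"""Generate coordinate fixtures with controlled hydrogen-bond geometry.

The pair-fixture generator places a backbone amide donor and a minimal
carbonyl acceptor at exact target values of the D-A distance, D-H-A angle
and H-A-AA angle, which makes criterion behavior easy to demonstrate.
"""

import tempfile
from pathlib import Path

from nucbond import FixtureSpec, detect_interface_hbonds, make_pair_fixture, read_structure

cases = [
    FixtureSpec(d_da=2.9, dha_deg=150.0, haaa_deg=120.0),  # comfortable bond
    FixtureSpec(d_da=3.1, dha_deg=130.0, haaa_deg=100.0),  # still a bond
    FixtureSpec(d_da=2.9, dha_deg=80.0, haaa_deg=120.0),   # D-H-A too acute
    FixtureSpec(d_da=3.5, dha_deg=150.0, haaa_deg=120.0),  # implies H-A = 2.6 A
]

with tempfile.TemporaryDirectory() as tmp:
    for spec in cases:
        path = Path(tmp) / "pair.pdb"
        path.write_text(make_pair_fixture(spec))
        bonds = detect_interface_hbonds(read_structure(path))
        verdict = (
            f"1 bond (H-A {bonds[0].d_ha:.2f} A, D-H-A {bonds[0].angle_dha:.1f} deg)"
            if bonds
            else "no bond"
        )
        print(
            f"targets D-A={spec.d_da} A, D-H-A={spec.dha_deg} deg, "
            f"H-A-AA={spec.haaa_deg} deg  ->  {verdict}"
        )

# The first two geometries satisfy all four criteria.  The third fails the
# D-H-A > 90 deg requirement outright; the fourth keeps D-A under 3.9 A but
# its implied hydrogen-acceptor distance exceeds the 2.5 A cutoff.
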