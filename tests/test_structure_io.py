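import numpy as np
import pytest

from nucbond.model import Chain, Residue
from nucbond.structure_io import (
    EmptyStructureError,
    classify_chain,
    read_structure,
    select_complex,
    write_pdb,
)

MINIMAL_ALA = """\
HEADER    TEST COMPLEX                            01-JAN-13   1ABC
EXPDTA    X-RAY DIFFRACTION
REMARK   2 RESOLUTION.    2.50 ANGSTROMS.
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.804   6.900  -5.510  1.00  0.00           C
ATOM      3  C   ALA A   1      11.704   6.300  -4.110  1.00  0.00           C
ATOM      4  O   ALA A   1      10.904   5.400  -3.910  1.00  0.00           O
ATOM      5  CB  ALA A   1      13.204   7.000  -6.010  1.00  0.00           C
END
"""


def test_minimal_pdb_is_echoed(parse_text):
    st = parse_text(MINIMAL_ALA)
    assert st.entry_id == "1ABC"
    assert st.method == "X-RAY DIFFRACTION"
    assert st.resolution == pytest.approx(2.5)
    assert len(st.chains) == 1
    (chain,) = st.chains
    assert chain.id == "A" and len(chain.residues) == 1
    assert len(chain.residues[0].atoms) == 5
    np.testing.assert_allclose(
        chain.residues[0].find_atom("N").position, [11.104, 6.134, -6.504]
    )


def test_highest_occupancy_altloc_kept(parse_text):
    text = MINIMAL_ALA.replace(
        "ATOM      2  CA  ALA A   1      11.804   6.900  -5.510  1.00  0.00           C",
        "ATOM      2  CA AALA A   1      11.804   6.900  -5.510  0.60  0.00           C\n"
        "ATOM      6  CA BALA A   1      11.904   7.000  -5.610  0.40  0.00           C",
    )
    st = parse_text(text)
    residue = st.chains[0].residues[0]
    cas = [a for a in residue.atoms if a.name == "CA"]
    assert len(cas) == 1
    assert cas[0].altloc == "A"
    assert cas[0].occupancy == pytest.approx(0.6)


def test_altloc_occupancy_tie_breaks_alphabetically(parse_text):
    text = MINIMAL_ALA.replace(
        "ATOM      2  CA  ALA A   1      11.804   6.900  -5.510  1.00  0.00           C",
        "ATOM      2  CA BALA A   1      11.904   7.000  -5.610  0.50  0.00           C\n"
        "ATOM      6  CA AALA A   1      11.804   6.900  -5.510  0.50  0.00           C",
    )
    st = parse_text(text)
    cas = [a for a in st.chains[0].residues[0].atoms if a.name == "CA"]
    assert len(cas) == 1 and cas[0].altloc == "A"


def test_empty_file_raises(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(EmptyStructureError):
        read_structure(path)


def test_waters_and_hetero_skipped_mse_aliased(parse_text):
    text = MINIMAL_ALA.replace(
        "END",
        "HETATM    6  O   HOH A 101      15.000  15.000  15.000  1.00  0.00           O\n"
        "HETATM    7  C1  XYZ A 102      16.000  16.000  16.000  1.00  0.00           C\n"
        "HETATM    8 SE   MSE A   2      18.000  18.000  18.000  1.00  0.00          SE\n"
        "END",
    )
    st = parse_text(text)
    names = [(r.name, [a.name for a in r.atoms]) for r in st.chains[0].residues]
    assert ("MET", ["SD"]) in names
    assert all(r.name not in ("HOH", "XYZ") for r in st.chains[0].residues)
    met = next(r for r in st.chains[0].residues if r.name == "MET")
    assert met.find_atom("SD").element.upper() == "SE"  # element preserved, name aliased


def test_file_hydrogens_dropped(parse_text):
    text = MINIMAL_ALA.replace(
        "END",
        "ATOM      6  H   ALA A   1      11.000   6.000  -7.000  1.00  0.00           H\n"
        "END",
    )
    st = parse_text(text)
    assert all(a.element != "H" for a in st.chains[0].residues[0].atoms)


@pytest.mark.parametrize(
    "names,expected",
    [
        (["ALA", "GLY", "ARG"], "protein"),
        (["DA", "DC", "DG"], "dna"),
        (["A", "C", "G", "U"], "rna"),
        (["HOH", "HOH"], "other"),
        (["ALA", "DA"], "other"),  # no majority
    ],
)
def test_classify_chain(names, expected):
    chain = Chain(id="X", residues=[Residue(name=n, seqid=i + 1) for i, n in enumerate(names)])
    assert classify_chain(chain) == expected


def test_classify_chain_order_invariant():
    names = ["ALA", "GLY", "DA", "ALA", "U"]
    fwd = Chain(id="X", residues=[Residue(name=n, seqid=i) for i, n in enumerate(names)])
    rev = Chain(id="X", residues=[Residue(name=n, seqid=i) for i, n in enumerate(reversed(names))])
    assert classify_chain(fwd) == classify_chain(rev)


def test_classify_empty_chain_raises():
    with pytest.raises(ValueError):
        classify_chain(Chain(id="X"))


class TestSelectComplex:
    def _complex(self, parse_text, resolution="2.50", method="X-RAY DIFFRACTION"):
        text = MINIMAL_ALA.replace("2.50", resolution).replace("X-RAY DIFFRACTION", method)
        text = text.replace(
            "END",
            "ATOM      6  O2' .C. R   8      10.000  10.000  10.000  1.00  0.00           O\n"
            "END",
        ).replace(".C.", "  C")
        return parse_text(text)

    def test_xray_good_resolution_kept(self, parse_text):
        assert select_complex(self._complex(parse_text)) is True

    def test_resolution_boundary_inclusive(self, parse_text):
        assert select_complex(self._complex(parse_text, resolution="3.00")) is True
        assert select_complex(self._complex(parse_text, resolution="3.10")) is False

    def test_nmr_rejected(self, parse_text):
        assert select_complex(self._complex(parse_text, method="SOLUTION NMR")) is False

    def test_protein_only_rejected(self, parse_text):
        assert select_complex(parse_text(MINIMAL_ALA)) is False


def test_parse_write_parse_is_identity(parse_text, tmp_path):
    from nucbond.fixtures import FixtureSpec, make_pair_fixture

    st1 = parse_text(make_pair_fixture(FixtureSpec(seed=5)))
    st2 = parse_text(write_pdb(st1), name="rewritten.pdb")
    assert st1.entry_id == st2.entry_id
    assert st1.resolution == st2.resolution
    assert [(c.id, c.kind) for c in st1.chains] == [(c.id, c.kind) for c in st2.chains]
    for c1, c2 in zip(st1.chains, st2.chains):
        for r1, r2 in zip(c1.residues, c2.residues):
            assert (r1.name, r1.seqid, r1.icode) == (r2.name, r2.seqid, r2.icode)
            assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
            for a1, a2 in zip(r1.atoms, r2.atoms):
                np.testing.assert_allclose(a1.position, a2.position, atol=1e-9)
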