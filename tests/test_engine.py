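import numpy as np
import pytest

from conftest import acceptor_chain, amide_probe_chain, build_structure
from nucbond.engine import (
    CriteriaConfig,
    candidate_pairs,
    collect_sites,
    detect_interface_hbonds,
    has_interface_hbond,
)
from nucbond.fixtures import FixtureSpec, brute_force_hbonds, make_pair_fixture

# The probe donor's inferred hydrogen sits exactly at (1, 0, 0); acceptor
# geometry below is expressed relative to that hydrogen.
H = np.array([1.0, 0.0, 0.0])


def probe(acc_offset, ant_offset):
    return build_structure(
        [amide_probe_chain(), acceptor_chain(H + acc_offset, H + acc_offset + ant_offset)]
    )


class TestCriteria:
    def test_favorable_geometry_accepted(self):
        # d_ha = 1.25, DHA = 143.1 deg, d_da = 2.14, HAAA = 143.1 deg
        st = probe(np.array([1.0, 0.75, 0.0]), np.array([0.0, 1.23, 0.0]))
        (bond,) = detect_interface_hbonds(st)
        assert bond.donor.atom_name == "N" and bond.acceptor.atom_name == "O4"
        assert bond.d_ha == pytest.approx(1.25)
        assert bond.angle_dha == pytest.approx(143.13, abs=0.01)

    def test_long_ha_distance_rejected(self):
        # d_ha = 2.6 with everything else favorable
        st = probe(np.array([1.56, 2.08, 0.0]), np.array([0.0, 1.23, 0.0]))
        assert detect_interface_hbonds(st) == []

    def test_acute_dha_angle_rejected(self):
        # acceptor on the donor side of the hydrogen: DHA = 60 deg
        st = probe(np.array([-1.0, 1.7320508, 0.0]), np.array([0.0, 1.23, 0.0]))
        assert detect_interface_hbonds(st) == []

    def test_haaa_angle_rejected_for_any_antecedent(self):
        # antecedent on the hydrogen side of the acceptor: HAAA small
        st = probe(np.array([1.0, 0.75, 0.0]), np.array([-0.8, -0.6, 0.0]))
        assert detect_interface_hbonds(st) == []

    def test_acceptor_without_antecedent_rejected(self):
        st = build_structure(
            [amide_probe_chain(), ("B", [("U", 1, {"O4": H + np.array([1.0, 0.75, 0.0])})])]
        )
        assert detect_interface_hbonds(st) == []


class TestBoundaries:
    """Strict inequalities: geometry exactly at a threshold yields no bond."""

    def test_ha_distance_boundary(self):
        # d_ha exactly 2.5 (3-4-5 triangle), DHA = 126.9 deg, d_da = 3.2
        st = probe(np.array([1.5, 2.0, 0.0]), np.array([0.0, 1.23, 0.0]))
        assert detect_interface_hbonds(st) == []
        # contrast: marginally inside
        st = probe(np.array([1.49, 2.0, 0.0]), np.array([0.0, 1.23, 0.0]))
        assert len(detect_interface_hbonds(st)) == 1

    def test_dha_angle_boundary(self):
        # acceptor perpendicular over the hydrogen: DHA exactly 90 deg
        st = probe(np.array([0.0, 2.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        assert detect_interface_hbonds(st) == []
        st = probe(np.array([0.1, 2.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        assert len(detect_interface_hbonds(st)) == 1

    def test_da_distance_boundary(self):
        # donor-acceptor distance exactly 3.9: not even a candidate pair
        st = build_structure(
            [
                amide_probe_chain(),
                acceptor_chain(np.array([3.9, 0.0, 0.0]), np.array([3.9, 1.23, 0.0])),
            ]
        )
        donors, acceptors = collect_sites(st)
        assert candidate_pairs(donors, acceptors, 3.9) == []
        assert detect_interface_hbonds(st) == []

    def test_haaa_angle_boundary(self):
        # antecedent perpendicular to the H-A direction: HAAA exactly 90 deg
        st = probe(np.array([1.0, 0.75, 0.0]), np.array([-0.75, 1.0, 0.0]))
        assert detect_interface_hbonds(st) == []
        st = probe(np.array([1.0, 0.75, 0.0]), np.array([-0.70, 1.0, 0.0]))
        assert len(detect_interface_hbonds(st)) == 1


class TestCandidatePairs:
    def test_pair_beyond_cutoff_absent(self):
        st = build_structure(
            [
                amide_probe_chain(),
                acceptor_chain(np.array([4.5, 0.0, 0.0]), np.array([4.5, 1.23, 0.0])),
            ]
        )
        donors, acceptors = collect_sites(st)
        assert candidate_pairs(donors, acceptors, 3.9) == []

    def test_same_molecule_pairs_excluded(self):
        # serine donor next to a backbone O acceptor, same protein chain
        st = build_structure(
            [
                (
                    "A",
                    [
                        ("SER", 1, {"N": [0, 0, 0], "CA": [1.46, 0, 0],
                                    "CB": [2.0, 1.4, 0], "OG": [1.5, 2.4, 1.0],
                                    "C": [2.2, -1.2, 0], "O": [2.0, -2.0, 1.9]}),
                    ],
                ),
            ]
        )
        donors, acceptors = collect_sites(st)
        assert donors and acceptors
        assert candidate_pairs(donors, acceptors, 3.9) == []

    def test_matches_all_pairs_scan_on_random_fixture(self, parse_text):
        from nucbond.fixtures import make_random_fixture

        st = parse_text(make_random_fixture(21))
        donors, acceptors = collect_sites(st)
        fast = set(candidate_pairs(donors, acceptors, 3.9))
        slow = {
            (i, j)
            for i, d in enumerate(donors)
            for j, a in enumerate(acceptors)
            if d.is_protein != a.is_protein
            and np.linalg.norm(d.atom.position - a.atom.position) < 3.9
        }
        assert fast == slow


class TestDetect:
    def test_protein_only_structure_empty(self):
        st = build_structure([amide_probe_chain()])
        assert detect_interface_hbonds(st) == []
        assert has_interface_hbond(st) is False

    def test_has_interface_hbond(self, parse_text):
        st = parse_text(make_pair_fixture(FixtureSpec()))
        assert has_interface_hbond(st) is True
        st = parse_text(make_pair_fixture(FixtureSpec(dha_deg=80.0)), name="f2.pdb")
        assert has_interface_hbond(st) is False

    def test_output_sorted_and_deterministic(self, parse_text):
        from nucbond.fixtures import make_random_fixture

        st = parse_text(make_random_fixture(2))
        bonds = detect_interface_hbonds(st)
        assert [b.sort_key() for b in bonds] == sorted(b.sort_key() for b in bonds)
        again = detect_interface_hbonds(parse_text(make_random_fixture(2), name="g.pdb"))
        assert [b.sort_key() for b in bonds] == [b.sort_key() for b in again]

    def test_triangle_consistency(self, parse_text):
        from nucbond.fixtures import make_random_fixture

        for seed in (1, 4, 6):
            st = parse_text(make_random_fixture(seed), name=f"t{seed}.pdb")
            for b in detect_interface_hbonds(st):
                d_dh = np.linalg.norm(
                    b.hydrogen
                    - next(
                        a.position
                        for c in st.chains
                        if c.id == b.donor.chain_id
                        for r in c.residues
                        if (r.seqid, r.icode) == (b.donor.seqid, b.donor.icode)
                        for a in r.atoms
                        if a.name == b.donor.atom_name
                    )
                )
                assert b.d_da <= d_dh + b.d_ha + 1e-9

    def test_rotor_donor_may_bond_multiple_acceptors(self):
        # one serine hydroxyl between two uracil carbonyls
        st = build_structure(
            [
                (
                    "A",
                    [
                        ("SER", 1, {"N": [-3.0, 0, 0], "CA": [-2.4, 1.3, 0],
                                    "CB": [-1.43, 0, 0], "OG": [0.0, 0.0, 0.0],
                                    "C": [-3.5, 2.2, 0], "O": [-4.5, 2.0, 0.8]}),
                    ],
                ),
                (
                    "B",
                    [
                        ("U", 1, {"O4": [2.0, 1.5, 0.0], "C4": [2.2, 2.7, 0.0]}),
                        ("U", 2, {"O4": [2.0, -1.5, 0.0], "C4": [2.2, -2.7, 0.0]}),
                    ],
                ),
            ]
        )
        bonds = detect_interface_hbonds(st)
        donors = {(b.donor.atom_name, b.acceptor.seqid) for b in bonds}
        assert donors == {("OG", 1), ("OG", 2)}


def test_invalid_criteria_rejected():
    with pytest.raises(ValueError):
        CriteriaConfig(max_ha=-1.0)
    with pytest.raises(ValueError):
        CriteriaConfig(max_ha=4.0, max_da=3.9)


def test_engine_equals_brute_force_oracle(parse_text):
    from nucbond.fixtures import make_random_fixture

    for seed in range(10):
        st = parse_text(make_random_fixture(seed), name=f"o{seed}.pdb")
        fast = detect_interface_hbonds(st)
        slow = brute_force_hbonds(st)
        assert [(b.donor, b.acceptor) for b in fast] == [(b.donor, b.acceptor) for b in slow]
        for x, y in zip(fast, slow):
            assert x.d_ha == pytest.approx(y.d_ha, abs=1e-9)
            assert x.angle_dha == pytest.approx(y.angle_dha, abs=1e-9)
            assert x.angle_haaa == pytest.approx(y.angle_haaa, abs=1e-9)
            assert x.antecedent == y.antecedent
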