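"""Backbone hydrogen-bond detection and alpha/pi/defect classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poregate as pg
from poregate.geometry import reconstruct_amide_hydrogens, rotation_about_axis
from poregate.helix import BackboneHBond, dssp_energy


class TestDetectBackboneHbonds:
    def test_ideal_alpha_gives_eleven_i4_bonds(self, alpha_helix_15):
        bonds = pg.detect_backbone_hbonds(alpha_helix_15)
        assert len(bonds) == 11
        assert all(b.offset == 4 for b in bonds)
        donors = sorted(b.donor_residue[1] for b in bonds)
        assert donors == list(range(5, 16))

    def test_ideal_pi_gives_only_i5_bonds(self, pi_helix_15):
        bonds = pg.detect_backbone_hbonds(pi_helix_15)
        assert bonds and all(b.offset == 5 for b in bonds)

    def test_ideal_three_ten_gives_only_i3_bonds(self):
        st_ = pg.make_ideal_helix(12, "three_ten")
        bonds = pg.detect_backbone_hbonds(st_)
        assert bonds and all(b.offset == 3 for b in bonds)

    def test_two_residue_peptide_has_no_bonds(self):
        st_ = pg.make_ideal_helix(2, "alpha")
        assert pg.detect_backbone_hbonds(st_) == []

    def test_four_residue_alpha_has_no_i4_bonds(self):
        st_ = pg.make_ideal_helix(4, "alpha")
        assert pg.detect_backbone_hbonds(st_) == []

    def test_geometric_criterion_agrees_on_ideal_alpha(self, alpha_helix_15):
        bonds = pg.detect_backbone_hbonds(alpha_helix_15, criterion="geom")
        assert {(b.donor_residue, b.acceptor_residue) for b in bonds} >= {
            (("A", i), ("A", i - 4)) for i in range(6, 16)}

    def test_matches_brute_force_all_pairs_search(self, pi_helix_15):
        """Best-per-donor detection equals an independent all-pairs scan."""
        bonds = pg.detect_backbone_hbonds(pi_helix_15)
        atoms = {}
        for n, r, c in zip(pi_helix_15.name, pi_helix_15.residue_number,
                           pi_helix_15.coord):
            atoms[(int(r), str(n))] = c
        nres = int(pi_helix_15.residue_number.max())
        expected = {}
        for don in range(2, nres + 1):
            h = reconstruct_amide_hydrogens(atoms[(don, "N")], atoms[(don, "CA")],
                                            atoms[(don - 1, "C")])
            best = None
            for acc in range(1, don - 1):
                e = dssp_energy(atoms[(don, "N")], h, atoms[(acc, "C")],
                                atoms[(acc, "O")])
                if e < -0.5 and (best is None or (e, don - acc) < best[:2]):
                    best = (e, don - acc, acc)
            if best:
                expected[("A", don)] = (("A", best[2]), best[1])
        got = {b.donor_residue: (b.acceptor_residue, b.offset) for b in bonds}
        assert got == expected

    def test_offset_histogram_rigid_motion_invariant(self, alpha_helix_15):
        rot = rotation_about_axis([1.0, 2.0, 0.5], 73.0)
        moved = alpha_helix_15.with_coord(alpha_helix_15.coord @ rot.T
                                          + np.array([5.0, -3.0, 12.0]))
        ref = sorted(b.offset for b in pg.detect_backbone_hbonds(alpha_helix_15))
        new = sorted(b.offset for b in pg.detect_backbone_hbonds(moved))
        assert ref == new

    def test_unknown_criterion_rejected(self, alpha_helix_15):
        with pytest.raises(ValueError):
            pg.detect_backbone_hbonds(alpha_helix_15, criterion="magic")


def _alpha_bond(donor, acceptor):
    return BackboneHBond(("A", donor), ("A", acceptor), donor - acceptor, -2.0)


class TestClassifyHelixPattern:
    SEGMENT = [("A", i) for i in range(200, 215)]

    def test_all_offset4_is_all_alpha(self):
        bonds = [_alpha_bond(i, i - 4) for i in range(204, 215)]
        ann = pg.classify_helix_pattern(bonds, self.SEGMENT)
        assert set(ann.labels.values()) == {"alpha"}
        assert ann.defect_segments == []

    def test_removed_i4_run_with_i5_replacement(self):
        """Breaking donors 210..214 and adding 212->207 (i+5) yields pi labels
        at the i+5 participants and defect runs across the transition."""
        bonds = [_alpha_bond(i, i - 4) for i in range(204, 215)
                 if i not in range(210, 215)]
        bonds.append(BackboneHBond(("A", 212), ("A", 207), 5, -2.0))
        ann = pg.classify_helix_pattern(bonds, self.SEGMENT)
        assert ann.labels[("A", 212)] == "pi"
        assert ann.labels[("A", 207)] == "pi"
        defect_residues = {r for r, lab in ann.labels.items() if lab == "defect"}
        assert defect_residues == {("A", 210), ("A", 211), ("A", 213), ("A", 214)}
        assert (("A", 210), ("A", 211)) in ann.defect_segments
        assert (("A", 213), ("A", 214)) in ann.defect_segments
        # 210's carbonyl lost its partner and nothing replaced it
        assert ("A", 210) in ann.unpaired_carbonyls

    def test_alpha_then_pi_run_has_single_defect_boundary(self):
        """Mixed register, alpha donors below and pi donors above the change.

        Brute-force over the constructed bond pattern: residue 210 is the
        only one participating in no bond (its would-be donors 214/215
        donate elsewhere or lie outside), so exactly one single-residue
        defect segment marks the register change.
        """
        bonds = [_alpha_bond(i, i - 4) for i in range(204, 208)]
        bonds += [BackboneHBond(("A", i), ("A", i - 5), 5, -2.0)
                  for i in range(211, 215)]
        participating = {r for b in bonds for r in (b.donor_residue, b.acceptor_residue)}
        silent = [r for r in self.SEGMENT if r not in participating]
        assert silent == [("A", 210)]
        ann = pg.classify_helix_pattern(bonds, self.SEGMENT)
        # 208/209 still accept pi bonds in this pattern; only 210 is bare
        assert ann.defect_segments == [(("A", 210), ("A", 210))]

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            pg.classify_helix_pattern([], [])

    def test_ideal_helices_classified_as_their_generating_class(
            self, alpha_helix_15, pi_helix_15):
        for st_, expect in ((alpha_helix_15, "alpha"), (pi_helix_15, "pi")):
            ann, _ = pg.annotate_helix(st_)
            interior = [ann.labels[("A", i)] for i in range(6, 11)]
            assert set(interior) == {expect}


def _asn_fixture(partner_offset=-4, pull_away=False):
    """Asn with sidechain amide donating to a backbone carbonyl.

    Constructed so ND2-H...O has donor-acceptor 2.89 Angstrom and a
    D-H...A angle of 165 degrees.
    """
    o = np.array([0.0, 0.0, 0.0])
    h = np.array([0.0, 0.0, 1.9])
    hn = np.array([np.sin(np.deg2rad(15.0)), 0.0, np.cos(np.deg2rad(15.0))])
    nd2 = h + 1.01 * hn
    if pull_away:
        nd2 = nd2 + np.array([0.0, 0.0, 8.0])
        h = h + np.array([0.0, 0.0, 8.0])
    cg = nd2 + np.array([1.1, 0.6, 0.2])
    od1 = cg + np.array([0.4, 1.1, 0.0])
    ca = cg + np.array([1.0, 1.0, 1.0])
    c_bb = o + np.array([1.23, 0.0, 0.0])
    asn_num = 212
    partner_num = asn_num + partner_offset
    rows = [
        (1, "C", "C", "ALA", partner_num, c_bb),
        (2, "O", "O", "ALA", partner_num, o),
        (3, "CA", "C", "ASN", asn_num, ca),
        (4, "CG", "C", "ASN", asn_num, cg),
        (5, "OD1", "O", "ASN", asn_num, od1),
        (6, "ND2", "N", "ASN", asn_num, nd2),
        (7, "HD21", "H", "ASN", asn_num, h),
    ]
    st_ = pg.Structure(
        serial=[r[0] for r in rows], name=[r[1] for r in rows],
        element=[r[2] for r in rows], residue_name=[r[3] for r in rows],
        residue_number=[r[4] for r in rows], chain_id=["A"] * len(rows),
        coord=[r[5] for r in rows])
    return st_, ("A", asn_num)


class TestAsnSidechainHbond:
    def test_constructed_geometry_hits_minus_four_partner(self):
        st_, asn = _asn_fixture()
        hits = pg.detect_asn_sidechain_hbond(st_, asn)
        assert hits == [(("A", 208), -4)]

    def test_sidechain_pointing_into_bulk_finds_nothing(self):
        st_, asn = _asn_fixture(pull_away=True)
        assert pg.detect_asn_sidechain_hbond(st_, asn) == []

    def test_alanine_rejected_by_name(self, alpha_helix_15):
        with pytest.raises(ValueError, match="sidechain amide"):
            pg.detect_asn_sidechain_hbond(alpha_helix_15, ("A", 5))


@settings(deadline=None, derandomize=True)
@given(angle=st.floats(0.0, 360.0),
       axis_seed=st.integers(0, 2**16))
def test_bond_detection_invariant_under_random_rigid_motion(angle, axis_seed):
    helix = pg.make_ideal_helix(10, "alpha")
    rng = np.random.default_rng(axis_seed)
    ax = rng.normal(size=3)
    if np.linalg.norm(ax) < 1e-6:
        ax = np.array([0.0, 0.0, 1.0])
    rot = rotation_about_axis(ax, angle)
    moved = helix.with_coord(helix.coord @ rot.T + rng.normal(scale=20.0, size=3))
    ref = {(b.donor_residue, b.acceptor_residue) for b in pg.detect_backbone_hbonds(helix)}
    new = {(b.donor_residue, b.acceptor_residue) for b in pg.detect_backbone_hbonds(moved)}
    assert ref == new
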