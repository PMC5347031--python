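"""Ideal-helix construction, rotamers, and the salt-bridge geometry rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sahelix.sequences import PolypeptideSequence, ChargePairing
from sahelix.helixgeom import (
    build_ideal_helix, measure_phi_psi, measure_chi, set_chi,
    classify_rotamer, normalize_angle, RotamerState, UndefinedAngleError,
    salt_bridge_geometry, detect_clash, rotamer_combination_scan,
    MissingAtomError, HelixStructure, BIN_ANGLE,
)


def brute_force_bridge(structure, pairing):
    """Oracle: exhaustive scan over the named N/O atoms."""
    first, second, _ = pairing.mode.split("->")[0], None, None
    e_res = (pairing.donor_index if pairing.mode.startswith("E")
             else pairing.partner_index)
    x_res = (pairing.partner_index if pairing.mode.startswith("E")
             else pairing.donor_index)
    x_letter = pairing.mode.replace("E", "").replace("->", "")[0]
    oe = np.array([structure.atom_coord(e_res, "OE1"),
                   structure.atom_coord(e_res, "OE2")])
    centroid = oe.mean(axis=0)
    names = ["NZ"] if x_letter == "K" else ["NE", "NH1", "NH2"]
    best = min((float(np.linalg.norm(structure.atom_coord(x_res, nm) - centroid)), nm)
               for nm in names)
    return best


class TestBuildIdealHelix:
    def test_backbone_dihedrals(self, ala12):
        for rid in range(2, 12):
            phi, psi = measure_phi_psi(ala12, rid)
            assert phi == pytest.approx(-57.0, abs=0.5)
            assert psi == pytest.approx(-47.0, abs=0.5)

    def test_backbone_bond_lengths_physical(self, ala12):
        atoms = ala12.atoms
        for rid in range(1, 12):
            n = ala12.atom_coord(rid, "N")
            ca = ala12.atom_coord(rid, "CA")
            c = ala12.atom_coord(rid, "C")
            for d in (np.linalg.norm(ca - n), np.linalg.norm(c - ca)):
                assert 1.2 < d < 1.6

    def test_end_to_end_distance_of_98mer(self, ek3_helix):
        """End-to-end CA-CA length ~ 97 x ~1.5 A helical rise."""
        ca1 = ek3_helix.atom_coord(1, "CA")
        ca98 = ek3_helix.atom_coord(98, "CA")
        d = float(np.linalg.norm(ca98 - ca1))
        # axial-rise oracle: CA1-CA73 spans 72 residues = 20 exact turns at
        # 3.6 residues/turn, so the chord is purely axial
        rise = float(np.linalg.norm(
            ek3_helix.atom_coord(73, "CA") - ca1)) / 72
        assert d == pytest.approx(97 * rise, rel=0.02)
        assert d == pytest.approx(97 * 1.5, rel=0.1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_helix("")

    def test_rotamer_for_alanine_rejected(self):
        with pytest.raises(UndefinedAngleError):
            build_ideal_helix("AAA", rotamers={2: RotamerState(180, 180)})

    def test_sidechain_atoms_present(self, ek3_helix):
        seq = ek3_helix.sequence
        for rid, letter in enumerate(seq, start=1):
            if letter == "E":
                ek3_helix.atom_coord(rid, "OE1")
                ek3_helix.atom_coord(rid, "OE2")
            elif letter == "K":
                ek3_helix.atom_coord(rid, "NZ")


class TestChiPlacement:
    @pytest.mark.parametrize("letter,state", [
        ("K", RotamerState.from_bins("t", "t")),
        ("E", RotamerState.from_bins("g-", "g-")),
        ("R", RotamerState.from_bins("g+", "t")),
    ])
    def test_bin_placement_roundtrip(self, letter, state):
        h = build_ideal_helix("AA" + letter + "AA", rotamers={3: state})
        chi1, chi2 = measure_chi(h, 3)
        assert chi1 == pytest.approx(state.chi1, abs=1.0)
        assert chi2 == pytest.approx(state.chi2, abs=1.0)

    def test_random_roundtrip(self, rng):
        """Set-then-measure over random chi draws, 100 residue placements."""
        h = build_ideal_helix("AAKAAEAARAA")
        for _ in range(34):
            for rid in (3, 6, 9):
                chi1, chi2 = rng.uniform(-179, 179, size=2)
                set_chi(h, rid, 1, chi1)
                set_chi(h, rid, 2, chi2)
                got1, got2 = measure_chi(h, rid)
                assert got1 == pytest.approx(chi1, abs=1.0)
                assert got2 == pytest.approx(chi2, abs=1.0)

    def test_chi_undefined_for_gly(self):
        h = build_ideal_helix("AAGAA")
        with pytest.raises(UndefinedAngleError):
            measure_chi(h, 3)


class TestClassifyRotamer:
    @pytest.mark.parametrize("chi,expected", [
        (120.0, "t"), (-120.0, "t"), (180.0, "t"),
        (0.0, "g+"), (60.0, "g+"), (119.9, "g+"),
        (-119.9, "g-"), (-60.0, "g-"), (-0.001, "g-"),
    ])
    def test_boundaries(self, chi, expected):
        assert classify_rotamer(chi) == expected

    def test_partition_of_angle_space(self, rng):
        """Exactly one bin fires for every angle in (-180, 180]."""
        angles = rng.uniform(-180, 180, size=1_000_000)
        bins = np.array([0, 0, 0])
        key = {"t": 0, "g+": 1, "g-": 2}
        # vectorized reimplementation cross-checked against the scalar rule
        t = (angles >= 120) | (angles <= -120)
        gp = (angles >= 0) & (angles < 120)
        gm = (angles > -120) & (angles < 0)
        assert np.all(t.astype(int) + gp.astype(int) + gm.astype(int) == 1)
        for chi in rng.uniform(-180, 180, size=200):
            assert sum(classify_rotamer(chi) == b for b in ("t", "g+", "g-")) == 1

    @given(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_normalization_idempotent(self, angle):
        a = normalize_angle(angle)
        assert -180 < a <= 180
        assert classify_rotamer(angle) == classify_rotamer(a)


class TestSaltBridgeGeometry:
    def _pair_structure(self, x_letter="K", rotamers=None):
        seq = "AAEAA" + x_letter + "AA"
        return build_ideal_helix(seq, rotamers=rotamers), ChargePairing(
            donor_index=3, partner_index=6, mode=f"E->{x_letter}(+3)")

    def test_boundary_is_strict(self):
        """A distance of exactly 4.0 A is not a salt bridge."""
        from sahelix.helixgeom import is_salt_bridge_distance
        assert not is_salt_bridge_distance(4.0)
        assert is_salt_bridge_distance(3.999999)
        # and through coordinates, just off the boundary on either side
        h, pairing = self._pair_structure("K")
        centroid = 0.5 * (h.atom_coord(3, "OE1") + h.atom_coord(3, "OE2"))
        nz_mask = (h.atoms.res_id == 6) & (h.atoms.atom_name == "NZ")
        direction = h.atoms.coord[nz_mask][0] - centroid
        direction /= np.linalg.norm(direction)
        h.atoms.coord[nz_mask] = centroid + 4.001 * direction
        geom = salt_bridge_geometry(h, pairing)
        assert geom.distance == pytest.approx(4.001, abs=1e-4)
        assert not geom.formed
        h.atoms.coord[nz_mask] = centroid + 3.9 * direction
        assert salt_bridge_geometry(h, pairing).formed

    def test_arg_uses_minimum_nitrogen_distance(self):
        h, pairing = self._pair_structure("R")
        centroid = 0.5 * (h.atom_coord(3, "OE1") + h.atom_coord(3, "OE2"))
        for nm, d in (("NE", 5.0), ("NH1", 3.5), ("NH2", 6.0)):
            mask = (h.atoms.res_id == 6) & (h.atoms.atom_name == nm)
            vec = h.atoms.coord[mask][0] - centroid
            h.atoms.coord[mask] = centroid + d * vec / np.linalg.norm(vec)
        geom = salt_bridge_geometry(h, pairing)
        assert geom.distance == pytest.approx(3.5, abs=1e-6)
        assert geom.contributing_atom == "NH1"
        assert geom.formed

    def test_missing_sidechain_atom_raises(self):
        h, pairing = self._pair_structure("K")
        keep = ~((h.atoms.res_id == 6) & (h.atoms.atom_name == "NZ"))
        h2 = HelixStructure(atoms=h.atoms[keep])
        with pytest.raises(MissingAtomError):
            salt_bridge_geometry(h2, pairing)

    def test_matches_brute_force_on_randomized_structures(self, rng):
        h, pairing = self._pair_structure("R")
        for _ in range(100):
            j = h.copy()
            j.atoms.coord += rng.normal(0, 1.0, size=j.atoms.coord.shape)
            geom = salt_bridge_geometry(j, pairing)
            d, nm = brute_force_bridge(j, pairing)
            assert geom.distance == pytest.approx(d, abs=1e-9)
            assert geom.contributing_atom == nm
            assert geom.formed == (d < 4.0)


class TestDetectClash:
    def test_strict_boundary(self):
        h = build_ideal_helix("AAEAAKAA")
        pairing = ChargePairing(3, 6, "E->K(+3)")
        a = h.residue_coords(3)
        b = h.residue_coords(6)
        dmin = np.linalg.norm(a[:, None] - b[None, :], axis=-1).min()
        # push residue 6 along the min-distance direction to exactly 2.5/2.4
        for target, expected in ((2.5, False), (2.4, True)):
            j = h.copy()
            shift = (dmin - target)
            ii, jj = np.unravel_index(
                np.argmin(np.linalg.norm(a[:, None] - b[None, :], axis=-1)),
                (len(a), len(b)))
            direction = (a[ii] - b[jj]) / np.linalg.norm(a[ii] - b[jj])
            mask = j.atoms.res_id == 6
            j.atoms.coord[mask] += direction * shift
            assert detect_clash(j, pairing) is expected

    def test_ideal_separated_pair_has_no_clash(self):
        h = build_ideal_helix("AAEAAAKAA")
        pairing = ChargePairing(3, 7, "E->K(+4)")
        assert not detect_clash(h, pairing)
        # all-pairs distance oracle
        a = h.residue_coords(3)
        b = h.residue_coords(7)
        assert np.linalg.norm(a[:, None] - b[None, :], axis=-1).min() >= 2.5


@pytest.fixture(scope="module")
def ek3_scan():
    return rotamer_combination_scan("E->K(+3)")


class TestRotamerCombinationScan:
    def test_81_rows_per_mode(self, ek3_scan):
        assert len(ek3_scan) == 81
        assert len({(r.e_bins, r.x_bins) for r in ek3_scan}) == 81

    def test_capable_rows_satisfy_both_rules(self, ek3_scan):
        for r in ek3_scan:
            if r.capable:
                assert r.distance < 4.0
                assert not r.clash

    def test_capable_pose_reproducible_from_reported_chis(self, ek3_scan):
        """Rebuilding the reported pose reproduces formed & clash-free."""
        capable = [r for r in ek3_scan if r.capable]
        assert capable
        r = capable[0]
        h = build_ideal_helix("AAAAEAAKAAAA")
        pairing = ChargePairing(5, 8, "E->K(+3)")
        for k, val in enumerate(r.e_chi):
            set_chi(h, 5, k + 1, val)
        for k, val in enumerate(r.x_chi):
            set_chi(h, 8, k + 1, val)
        geom = salt_bridge_geometry(h, pairing)
        assert geom.formed
        assert not detect_clash(h, pairing)
        assert geom.distance == pytest.approx(r.distance, abs=0.05)

    def test_deterministic(self):
        a = rotamer_combination_scan("E->R(+4)")
        b = rotamer_combination_scan("E->R(+4)")
        assert [(r.e_bins, r.x_bins, r.distance, r.capable) for r in a] == \
               [(r.e_bins, r.x_bins, r.distance, r.capable) for r in b]

    def test_every_mode_has_capable_combinations(self):
        from sahelix.synth import mode_palettes
        for mode in ("E->K(+3)", "K->E(+4)", "E->R(+3)", "R->E(+4)"):
            on, off = mode_palettes(mode)
            assert on and off
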