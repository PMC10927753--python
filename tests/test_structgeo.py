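"""Geometry detectors: planted fixtures, brute-force oracles, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vuscope import structgeo as sg
from vuscope import synth
from vuscope.structgeo import (
    NotApplicableError, PDBFormatError, Structure, find_cation_pi,
    find_hbonds, find_salt_bridges, min_interchain_distance, parse_pdb,
    relative_exposure, substitution_clash_screen, write_pdb,
)


from geometry_oracles import (
    brute_cation_pi, brute_hbonds, brute_salt_bridges, random_residue_fixture,
)


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-50, 50, 3)
    return rot, trans


# ---------------------------------------------------------------------------

class TestPlantedDetections:
    def test_hbond_detected_at_exact_distance(self):
        s = synth.gen_structure("planted_interactions", {"hbond_distance": 2.7})
        records = find_hbonds(s)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(2.70, abs=1e-9)

    def test_hbond_beyond_cutoff_not_detected(self):
        s = synth.gen_structure("planted_interactions", {"hbond_distance": 3.8})
        assert find_hbonds(s) == []

    def test_interchain_salt_bridge(self):
        s = synth.gen_structure("planted_interactions",
                                {"salt_bridge_distance": 3.5,
                                 "salt_bridge_interchain": True})
        records = find_salt_bridges(s)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.5)
        assert records[0].interchain

    def test_salt_bridge_beyond_cutoff(self):
        s = synth.gen_structure("planted_interactions",
                                {"salt_bridge_distance": 5.0})
        assert find_salt_bridges(s) == []

    def test_cation_above_ring_face(self):
        s = synth.gen_structure("planted_interactions",
                                {"cation_pi_distance": 4.0,
                                 "cation_pi_angle_deg": 0.0})
        records = find_cation_pi(s)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(4.0)
        assert records[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_cation_in_ring_plane_rejected(self):
        s = synth.gen_structure("planted_interactions",
                                {"cation_pi_distance": 4.0,
                                 "cation_pi_angle_deg": 90.0})
        assert find_cation_pi(s) == []

    def test_histidine_can_act_as_cation(self):
        s = synth.gen_structure("planted_interactions",
                                {"buried_his": False, "exposed_his": True,
                                 "cation_pi_distance": 4.0,
                                 "cation_pi_angle_deg": 0.0})
        # exposed HIS is isolated: the planted LYS/PHE pair is the only hit
        with_his = find_cation_pi(s, his_as_cation=True)
        without = find_cation_pi(s, his_as_cation=False)
        assert len(with_his) >= len(without)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_hbond_oracle(self, seed):
        s = random_residue_fixture(50, seed)
        got = {(r.partner_a[0], r.partner_a[1], r.partner_a[3],
                r.partner_b[0], r.partner_b[1], r.partner_b[3])
               for r in find_hbonds(s)}
        assert got == brute_hbonds(s)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_salt_bridge_oracle(self, seed):
        s = random_residue_fixture(50, seed)
        got = {(r.partner_a[0], r.partner_a[1], r.partner_b[0], r.partner_b[1])
               for r in find_salt_bridges(s)}
        assert got == brute_salt_bridges(s)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_cation_pi_oracle(self, seed):
        s = random_residue_fixture(50, seed)
        got = {(r.partner_a[0], r.partner_a[1], r.partner_b[0], r.partner_b[1])
               for r in find_cation_pi(s)}
        assert got == brute_cation_pi(s)

    def test_min_interchain_distance_oracle(self):
        s = random_residue_fixture(30, 3)
        other = s.coord[(s.chain_id == "B") & s.heavy]
        for chain, rid, _ in s.residues():
            if chain != "A":
                continue
            mine = s.coord[s.residue_mask(chain, rid) & s.heavy]
            brute = min(np.linalg.norm(a - b) for a in mine for b in other)
            assert min_interchain_distance(s, (chain, rid)) == pytest.approx(brute)


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", [7, 8])
    def test_detectors_invariant_under_rigid_motion(self, seed):
        s = random_residue_fixture(40, 5)
        rot, trans = random_rigid(seed)
        moved = s.transformed(rot, trans)
        for finder in (find_hbonds, find_salt_bridges, find_cation_pi):
            a, b = finder(s), finder(moved)
            assert len(a) == len(b)
            for ra, rb in zip(a, b):
                assert ra.partner_a == rb.partner_a
                assert ra.distance == pytest.approx(rb.distance, abs=1e-6)
                if ra.angle is not None:
                    assert ra.angle == pytest.approx(rb.angle, abs=1e-4)

    def test_interchain_distance_invariant(self):
        s = synth.gen_structure("toy_dimer", {"min_distance": 6.0})
        rot, trans = random_rigid(13)
        moved = s.transformed(rot, trans)
        res = ("A", 5)
        assert (min_interchain_distance(moved, res)
                == pytest.approx(min_interchain_distance(s, res), abs=1e-6))


class TestDimerGeometry:
    def test_planted_separation_recovered_exactly(self):
        s = synth.gen_structure("toy_dimer", {"min_distance": 12.0})
        best = min(min_interchain_distance(s, ("A", r))
                   for c, r, _ in s.residues() if c == "A")
        assert best == pytest.approx(12.0, abs=1e-6)

    def test_contact_interface(self):
        s = synth.gen_structure("toy_dimer", {"min_distance": 3.8})
        best = min(min_interchain_distance(s, ("A", r))
                   for c, r, _ in s.residues() if c == "A")
        assert best == pytest.approx(3.8, abs=1e-6)

    def test_single_chain_not_applicable(self, helix):
        with pytest.raises(NotApplicableError):
            min_interchain_distance(helix, ("A", 1))


class TestExposure:
    def test_isolated_residue_fully_exposed(self):
        s = synth.gen_structure("planted_interactions", {"exposed_his": True})
        ratio, label = relative_exposure(s, ("A", 8))
        assert ratio >= 0.9
        assert label == "exposed"

    def test_caged_residue_buried(self):
        s = synth.gen_structure("planted_interactions", {"buried_his": True})
        ratio, label = relative_exposure(s, ("A", 7))
        assert ratio <= 0.05
        assert label == "buried"

    def test_exposure_decreases_as_occluders_added(self):
        base = synth.gen_structure("planted_interactions", {"exposed_his": True})
        ratio0, _ = relative_exposure(base, ("A", 8))
        his = synth._his_residue("A", 8, (260.0, 0.0, 0.0))
        side = np.array([c for n, c in zip(his["atom_name"], his["coord"])
                         if n not in ("N", "CA", "C", "O")])
        cage = synth._cage_block(side.mean(axis=0), "A", 200,
                                 radii=(6.0,), counts=(20,))
        crowded = synth._merge([his] + cage)
        ratio1, _ = relative_exposure(crowded, ("A", 8))
        assert ratio1 < ratio0

    def test_per_atom_sasa_additivity(self, helix):
        per_atom = sg.sasa_per_atom(helix)
        half = helix.res_id <= 12
        assert per_atom.sum() == pytest.approx(
            per_atom[half].sum() + per_atom[~half].sum(), rel=1e-9)


class TestClashScreen:
    def test_shrinking_substitution_never_flagged(self):
        s = synth.gen_structure("planted_interactions", {"buried_his": True})
        report = substitution_clash_screen(s, ("A", 7), "GLY")
        assert report.delta_volume < 0
        assert not report.potential_clash

    def test_bulkier_in_buried_spot_flagged(self):
        s = synth.gen_structure("planted_interactions", {"buried_his": True})
        report = substitution_clash_screen(s, ("A", 7), "TYR")
        assert report.delta_volume > 0
        assert report.neighbor_count >= report.density_threshold
        assert report.potential_clash

    def test_bulkier_at_exposed_spot_not_flagged(self):
        s = synth.gen_structure("planted_interactions", {"exposed_his": True})
        report = substitution_clash_screen(s, ("A", 8), "TYR")
        assert report.neighbor_count < report.density_threshold
        assert not report.potential_clash


class TestPdbIO:
    def test_round_trip_to_pdb_precision(self, tmp_path, helix):
        p = tmp_path / "h.pdb"
        write_pdb(helix, p)
        again = parse_pdb(p)
        assert again.n_atoms == helix.n_atoms
        np.testing.assert_allclose(again.coord, helix.coord, atol=1.5e-3)

    def test_multi_model_file(self, tmp_path, helix):
        from vuscope import trajstab
        traj = synth.gen_trajectory(helix, "stable", 3, 0.2, seed=1)
        p = tmp_path / "t.pdb"
        trajstab.write_trajectory(traj, p)
        s = parse_pdb(p)
        assert len(s.models) == 3

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = (
            "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA BSER A   1       9.000   0.000   0.000  0.40  0.00           C\n"
            "END\n")
        p = tmp_path / "a.pdb"
        p.write_text(pdb)
        s = parse_pdb(p)
        ca = s.coord[s.atom_name == "CA"]
        assert len(ca) == 1
        assert ca[0][0] == pytest.approx(1.0)

    def test_no_atom_records_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(PDBFormatError):
            parse_pdb(p)
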