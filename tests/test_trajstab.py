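"""Trajectory metrics, clustering and stability verdicts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vuscope import synth, trajstab
from vuscope.trajstab import (
    ClusterAssignment, DegenerateSelectionError, StabilityVerdict, Trajectory,
    TrajectoryInputError, cluster_frames, dimer_state, global_series,
    load_trajectory, local_selection, replica_summary, rmsd_matrix, rmsf,
    stability_verdict, superpose, tm_score, write_trajectory,
)

SITE = ("A", 12)


@pytest.fixture(scope="module")
def ref():
    return synth.gen_structure("ideal_helix", {"length": 24})


@pytest.fixture(scope="module")
def departure_traj(ref):
    return synth.gen_trajectory(
        ref, "local_departure", 400, 0.5,
        {"site": SITE, "t0": 200, "displacement": 6.0}, seed=42)


class TestSuperpose:
    def test_identical_coordinates_zero_rmsd(self, ref):
        _, rmsd = superpose(ref.coord, ref.coord)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self, ref):
        rot = Rotation.random(random_state=3).as_matrix()
        moved = ref.coord @ rot.T + np.array([5.0, -3.0, 11.0])
        back, rmsd = superpose(moved, ref.coord)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(back, ref.coord, atol=1e-8)

    def test_optimality_over_random_rotations(self, ref):
        rng = np.random.default_rng(4)
        mobile = ref.coord + rng.normal(0, 1.0, ref.coord.shape)
        _, best = superpose(mobile, ref.coord)
        centered_m = mobile - mobile.mean(0)
        centered_r = ref.coord - ref.coord.mean(0)
        for k in range(200):
            rot = Rotation.random(random_state=k).as_matrix()
            trial = np.sqrt(((centered_m @ rot.T - centered_r) ** 2)
                            .sum(axis=1).mean()) / 10.0
            assert best <= trial + 1e-12

    def test_degenerate_selection_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateSelectionError):
            superpose(line, line + 1.0)

    def test_agrees_with_mdanalysis(self, ref):
        mda = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(8)
        mobile = ref.coord + rng.normal(0, 1.5, ref.coord.shape)
        _, mine = superpose(mobile, ref.coord)
        theirs = mda.rmsd(mobile, ref.coord, center=True, superposition=True)
        assert mine * 10.0 == pytest.approx(theirs, rel=1e-6)


class TestGlobalSeries:
    def test_zero_noise_trajectory_is_flat(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 5, 0.0, seed=0)
        df = global_series(traj, include_sasa=False, include_hbonds=False)
        assert df["rmsd"].max() == pytest.approx(0.0, abs=1e-10)
        assert (df["native_contact_fraction"] == 1.0).all()
        assert df["tm_score"].min() == pytest.approx(1.0)
        assert df.attrs["global_stable"]

    def test_moderate_noise_flagged_globally_stable(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 10, 0.5, seed=1)
        df = global_series(traj, include_sasa=False, include_hbonds=False)
        assert df.attrs["global_stable"]          # all-frame RMSD < 1.0 nm

    def test_dissociation_increases_radius_of_gyration(self):
        dimer = synth.gen_structure("toy_dimer", {"length": 12,
                                                  "min_distance": 3.5})
        traj = synth.gen_trajectory(
            dimer, "dissociation", 40, 0.0,
            {"t0": 10, "velocity": 1.0, "chain": "B"}, seed=2)
        df = global_series(traj, include_sasa=False, include_hbonds=False)
        rg = df["radius_of_gyration"].to_numpy()
        assert (np.diff(rg[10:]) > 0).all()
        assert rg[9] == pytest.approx(rg[0])

    def test_native_contacts_decrease_with_displacement(self, ref):
        fractions = []
        for disp in (0.0, 3.0, 8.0):
            traj = synth.gen_trajectory(
                ref, "local_departure", 4, 0.0,
                {"site": SITE, "t0": 2, "displacement": disp}, seed=3)
            fractions.append(
                trajstab.native_contact_fraction(traj)[-1])
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[2] < 1.0

    def test_ss_fractions_recover_helix(self, ref):
        assert trajstab.ss_fractions(ref.coord, ref)["alpha"] >= 0.9

    def test_tm_score_needs_more_than_15_residues(self):
        short = synth.gen_structure("ideal_helix", {"length": 10})
        ca = np.nonzero(short.atom_name == "CA")[0]
        with pytest.raises(ValueError):
            tm_score(short.coord, short.coord, ca)


class TestRmsf:
    def test_zero_noise_zero_rmsf(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 5, 0.0, seed=0)
        assert rmsf(traj)["rmsf"].max() == pytest.approx(0.0, abs=1e-10)

    def test_peak_rmsf_in_displaced_region(self):
        # long helix so the displaced neighbourhood is a minority and the
        # superposition stays anchored on the stationary majority
        long_ref = synth.gen_structure("ideal_helix", {"length": 48})
        site = ("A", 24)
        traj = synth.gen_trajectory(
            long_ref, "local_departure", 200, 0.3,
            {"site": site, "t0": 100, "displacement": 6.0}, seed=44)
        table = rmsf(traj)
        displaced = {r for _, r in local_selection(long_ref, site, 1.0)}
        peak = table.loc[table["rmsf"].idxmax(), "res_id"]
        assert peak in displaced

    def test_rmsf_scales_linearly_with_noise(self, ref):
        med = []
        for sigma in (0.5, 1.0):
            traj = synth.gen_trajectory(ref, "stable", 300, sigma, seed=9)
            med.append(rmsf(traj)["rmsf"].median())
        assert med[1] / med[0] == pytest.approx(2.0, rel=0.1)


class TestLocalSelection:
    def test_radius_zero_selects_only_site(self, ref):
        assert local_selection(ref, SITE, 0.0) == [SITE]

    def test_huge_radius_selects_everything(self, ref):
        sel = local_selection(ref, SITE, 100.0)
        assert len(sel) == len(ref.residues())

    def test_matches_brute_force(self, ref):
        sel = set(local_selection(ref, SITE, 1.0))
        site_xyz = ref.coord[ref.residue_mask(*SITE) & ref.heavy]
        brute = set()
        for c, r, _ in ref.residues():
            xyz = ref.coord[ref.residue_mask(c, r) & ref.heavy]
            d = min(np.linalg.norm(a - b) for a in xyz for b in site_xyz)
            if d <= 10.0:
                brute.add((c, r))
        assert sel == brute

    def test_missing_site_rejected(self, ref):
        with pytest.raises(KeyError):
            local_selection(ref, ("A", 999), 1.0)


class TestRmsdMatrix:
    def test_zero_noise_all_zero(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 6, 0.0, seed=0)
        m = rmsd_matrix(traj, local_selection(ref, SITE, 1.0))
        assert np.abs(m).max() == pytest.approx(0.0, abs=1e-7)

    def test_symmetric_nonnegative_zero_diagonal(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 20, 1.0, seed=5)
        m = rmsd_matrix(traj, local_selection(ref, SITE, 1.0))
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert (m >= 0).all()
        np.testing.assert_allclose(np.diag(m), 0, atol=1e-12)

    def test_two_state_block_structure(self, ref, departure_traj):
        m = rmsd_matrix(departure_traj, local_selection(ref, SITE, 1.0),
                        stride=4)
        t0 = 200 // 4
        within = np.concatenate([m[:t0, :t0].ravel(), m[t0:, t0:].ravel()])
        cross = m[:t0, t0:].ravel()
        assert cross.mean() > 3 * within.mean()

    def test_pairwise_matches_single_pair_kabsch(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 8, 1.0, seed=6)
        sel = local_selection(ref, SITE, 1.0)
        m = rmsd_matrix(traj, sel)
        idx = trajstab._selection_atom_indices(ref, sel)
        for i, j in ((0, 3), (2, 7), (5, 6)):
            _, rmsd = superpose(traj.frames[i][idx], traj.frames[j][idx])
            assert m[i, j] == pytest.approx(rmsd, abs=1e-9)


class TestClustering:
    def test_all_zero_matrix_single_cluster(self):
        assign = cluster_frames(np.zeros((10, 10)))
        assert assign.n_clusters == 1
        assert (assign.labels == 0).all()
        assert assign.basal_cluster == 0

    def test_planted_two_state_matrix(self):
        n, t0 = 40, 25
        m = np.full((n, n), 0.4)
        m[:t0, :t0] = 0.05
        m[t0:, t0:] = 0.05
        np.fill_diagonal(m, 0.0)
        assign = cluster_frames(m, cutoff=0.15)
        assert assign.n_clusters == 2
        assert len(set(assign.labels[:t0])) == 1
        assert len(set(assign.labels[t0:])) == 1
        assert assign.labels[0] != assign.labels[-1]

    def test_members_within_cutoff_of_medoid(self, ref, departure_traj):
        m = rmsd_matrix(departure_traj, local_selection(ref, SITE, 1.0),
                        stride=4)
        assign = cluster_frames(m, cutoff=0.15)
        for f, lab in enumerate(assign.labels):
            assert m[f, assign.medoids[lab]] <= 0.15 + 1e-12

    def test_deterministic_tie_break(self):
        m = np.full((4, 4), 1.0)
        np.fill_diagonal(m, 0.0)
        assign = cluster_frames(m, cutoff=0.5)
        # all isolated: clusters formed in frame order
        assert list(assign.labels) == [0, 1, 2, 3]
        assert assign.medoids == [0, 1, 2, 3]


class TestStabilityVerdict:
    def _assign(self, labels):
        return ClusterAssignment(np.asarray(labels), [0, 1], int(labels[0]),
                                 0.15)

    def test_all_basal_is_stable(self):
        v = stability_verdict(self._assign([0] * 20))
        assert v.verdict == "stable"
        assert v.final_outside_fraction == 0.0
        assert v.departure_frame is None

    def test_transient_excursion_returning_is_stable(self):
        labels = [0] * 8 + [1, 1] + [0] * 10
        v = stability_verdict(self._assign(labels))
        assert v.verdict == "stable"

    def test_sustained_terminal_departure_is_unstable(self):
        labels = [0] * 10 + [1] * 10
        v = stability_verdict(self._assign(labels))
        assert v.verdict == "unstable"
        assert v.departure_frame == 10

    def test_departure_frame_respects_stride(self):
        a = ClusterAssignment(np.array([0] * 10 + [1] * 10), [0, 10], 0,
                              0.15, stride=5)
        assert stability_verdict(a).departure_frame == 50

    def test_verdict_iff_outside_threshold(self):
        labels = [0] * 15 + [1, 0, 1, 1, 1]   # final window of 5: 4/5 outside
        v = stability_verdict(self._assign(labels))
        assert v.verdict == "unstable"
        assert v.final_outside_fraction == pytest.approx(0.8)

    def test_planted_departure_recovered(self, ref, departure_traj):
        verdicts = trajstab.analyze_replica(departure_traj, SITE, stride=2)
        assert len(verdicts) == 1
        v = verdicts[0]
        assert v.verdict == "unstable"
        assert abs(v.departure_frame - 200) <= 0.05 * 400


@pytest.fixture(scope="module")
def bound_dimer():
    return synth.gen_structure("toy_dimer", {"length": 16, "min_distance": 3.5})


class TestDimerState:

    def test_stable_dimer_bound(self, bound_dimer):
        traj = synth.gen_trajectory(bound_dimer, "stable", 60, 0.3, seed=7)
        assert dimer_state(traj) == "bound"

    def test_dissociation_unbound(self, bound_dimer):
        traj = synth.gen_trajectory(
            bound_dimer, "dissociation", 120, 0.3,
            {"t0": 30, "velocity": 0.5, "chain": "B"}, seed=8)
        assert dimer_state(traj) == "unbound"

    def test_state_depends_only_on_final_window(self, bound_dimer):
        # velocity so small the chains are still in contact at the end
        traj = synth.gen_trajectory(
            bound_dimer, "dissociation", 100, 0.1,
            {"t0": 95, "velocity": 0.05, "chain": "B"}, seed=9)
        assert dimer_state(traj) == "bound"

    def test_single_chain_not_applicable(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 4, 0.1, seed=1)
        with pytest.raises(trajstab.NotApplicableError):
            dimer_state(traj)


class TestReplicaSummary:
    def _verdict(self, rid, chain, verdict):
        return StabilityVerdict(rid, chain, verdict, None, 0.0)

    @pytest.mark.parametrize("stable,total,text", [
        (2, 3, "2/3 (67%)"), (3, 3, "3/3 (100%)"), (0, 3, "0/3 (0%)"),
        (1, 3, "1/3 (33%)"),
    ])
    def test_fraction_text(self, stable, total, text):
        vs = [self._verdict(f"r{i}", "all",
                            "stable" if i <= stable else "unstable")
              for i in range(1, total + 1)]
        assert replica_summary(vs).fraction_text == text

    def test_any_unstable_chain_makes_replica_unstable(self):
        vs = [self._verdict("r1", "A", "stable"),
              self._verdict("r1", "B", "unstable"),
              self._verdict("r2", "A", "stable"),
              self._verdict("r2", "B", "stable")]
        s = replica_summary(vs)
        assert s.n_stable == 1 and s.n_total == 2
        assert s.fraction_text == "1/2 (50%)"


class TestRigidInvariance:
    def test_metrics_invariant_under_global_transform(self, ref):
        traj = synth.gen_trajectory(ref, "stable", 10, 0.8, seed=11)
        rot = Rotation.random(random_state=12).as_matrix()
        trans = np.array([20.0, -5.0, 3.0])
        moved = Trajectory(ref, traj.frames @ rot.T + trans)
        sel = local_selection(ref, SITE, 1.0)
        np.testing.assert_allclose(rmsd_matrix(traj, sel),
                                   rmsd_matrix(moved, sel), atol=1e-7)
        np.testing.assert_allclose(
            trajstab.native_contact_fraction(traj),
            trajstab.native_contact_fraction(moved), atol=1e-12)


class TestTrajectoryIO:
    def test_round_trip(self, tmp_path, ref):
        traj = synth.gen_trajectory(ref, "stable", 4, 0.4, seed=13)
        tp, rp = tmp_path / "t.pdb", tmp_path / "r.pdb"
        write_trajectory(traj, tp)
        from vuscope.structgeo import write_pdb
        write_pdb(ref, rp)
        again = load_trajectory(tp, rp)
        assert again.n_frames == 4
        np.testing.assert_allclose(again.frames, traj.frames, atol=1.5e-3)

    def test_frame_order_preserved(self, tmp_path, ref):
        # plant a distinguishable per-frame displacement and confirm ordering
        frames = np.repeat(ref.coord[None], 5, axis=0)
        frames += np.arange(5)[:, None, None] * np.array([1.0, 0.0, 0.0])
        traj = Trajectory(ref, frames)
        tp, rp = tmp_path / "t.pdb", tmp_path / "r.pdb"
        write_trajectory(traj, tp)
        from vuscope.structgeo import write_pdb
        write_pdb(ref, rp)
        again = load_trajectory(tp, rp)
        shifts = again.frames[:, 0, 0] - again.frames[0, 0, 0]
        np.testing.assert_allclose(shifts, np.arange(5), atol=1e-2)

    def test_atom_count_mismatch_rejected(self, tmp_path, ref):
        short = synth.gen_structure("ideal_helix", {"length": 10})
        tp, rp = tmp_path / "t.pdb", tmp_path / "r.pdb"
        traj = synth.gen_trajectory(short, "stable", 3, 0.1, seed=1)
        write_trajectory(traj, tp)
        from vuscope.structgeo import write_pdb
        write_pdb(ref, rp)
        with pytest.raises(TrajectoryInputError):
            load_trajectory(tp, rp)

    def test_single_frame_rejected(self, ref):
        with pytest.raises(TrajectoryInputError):
            Trajectory(ref, ref.coord[None])
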