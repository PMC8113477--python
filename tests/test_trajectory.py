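"""Trajectory analyses: front, growth rate, census, binding, torsion,
hydration maps, hydrogen bonds, distance PDFs, RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from icepept import trajectory as ta
from icepept.geometry import dihedral, place_fourth_atom, superpose
from icepept.phase import classify_frameset
from icepept.synthetic import FrameSet


def _frameset(coords, species, box=(50.0, 50.0, 50.0), dt=1.0):
    coords = np.asarray(coords, dtype=float)
    times = np.arange(coords.shape[0]) * dt
    return FrameSet(coords, np.array(species, dtype=object),
                    np.asarray(box, float), times)


class TestFrontTracking:
    def test_scripted_front_recovered_within_bin(self, short_traj,
                                                 short_traj_labels):
        fs = ta.front_series(short_traj, short_traj_labels, bin_width=1.0)
        truth = short_traj.metadata["front_truth"]
        # constant classification lag is fine; spread around it must be small
        err = fs.front_z - truth
        assert np.std(err) < 1.5
        assert abs(np.mean(err)) < 3.0

    def test_all_ice_profile_hits_box_top(self, ice_lattice):
        from icepept.phase import classify_waters
        labels = classify_waters(ice_lattice.oxygen_positions, ice_lattice.box)
        with pytest.warns(UserWarning, match="ice"):
            z = ta.ice_front_profile(labels, ice_lattice.oxygen_positions[:, 2],
                                     float(ice_lattice.box[2]))
        assert z == pytest.approx(float(ice_lattice.box[2]))

    def test_all_liquid_profile_hits_bottom(self, liquid_box):
        from icepept.phase import classify_waters
        pos = liquid_box.water_oxygens(0)
        labels = classify_waters(pos, liquid_box.box)
        labels.labels[:] = "LIQ"
        with pytest.warns(UserWarning, match="liquid"):
            z = ta.ice_front_profile(labels, pos[:, 2], float(liquid_box.box[2]))
        assert z == 0.0

    def test_growth_property_starts_at_zero(self, short_traj, short_traj_labels):
        fs = ta.front_series(short_traj, short_traj_labels)
        assert fs.growth[0] == 0.0


class TestGrowthRate:
    def test_static_slab_rate_is_zero(self):
        fs = ta.FrontSeries(np.arange(20.0), np.full(20, 12.0))
        _, rate = ta.growth_rate(fs, smooth_window=5)
        assert np.allclose(rate, 0.0)

    def test_linear_front_rate_exact(self):
        t = np.arange(50.0)
        fs = ta.FrontSeries(t, 10.0 + 0.5 * t)
        rt, rate = ta.growth_rate(fs, smooth_window=7)
        assert np.allclose(rate, 0.5, atol=1e-9)
        assert len(rt) == len(rate) == 50 - 7 + 1

    def test_window_larger_than_series_is_an_error(self):
        fs = ta.FrontSeries(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            ta.growth_rate(fs, smooth_window=10)

    def test_post_binding_rate_drop_detected(self, short_traj,
                                             short_traj_labels):
        fs = ta.front_series(short_traj, short_traj_labels)
        rt, rate = ta.growth_rate(fs, smooth_window=5)
        t_bind = short_traj.metadata["t_bind"]
        pre = rate[(rt > 2.0) & (rt < t_bind - 2.0)].mean()
        post = rate[rt > t_bind + 5.0].mean()
        assert post < 0.5 * pre


class TestSolvationCensus:
    def test_counts_partition_shell(self, short_traj, short_traj_labels):
        census = ta.solvation_census(
            short_traj, short_traj_labels,
            int(short_traj.metadata["probe_index"]))
        assert (census.n_total == census.n_liquid + census.n_icelike).all()

    def test_mean_count_matches_density(self, liquid_box):
        """Probe in uniform liquid: mean shell count ≈ ρ·(4/3)πr³."""
        labels = classify_frameset(liquid_box)
        # use an arbitrary water as probe center (exclude itself ≈ -1)
        census = ta.solvation_census(liquid_box, labels, 0, r_shell=5.4)
        expected = 0.0334 * 4.0 / 3.0 * np.pi * 5.4**3
        assert abs(census.n_total[0] - expected) <= 3 * np.sqrt(expected) + 1

    def test_icelike_appears_only_after_binding(self, short_traj,
                                                short_traj_labels):
        census = ta.solvation_census(
            short_traj, short_traj_labels,
            int(short_traj.metadata["probe_index"]))
        t_bind = short_traj.metadata["t_bind"]
        pre = census.n_icelike[short_traj.times < t_bind - 1.0]
        post = census.n_icelike[short_traj.times >= t_bind]
        assert pre.mean() < 1.0
        assert post.mean() > 4.0

    def test_nonpositive_shell_is_an_error(self, short_traj, short_traj_labels):
        with pytest.raises(ValueError):
            ta.solvation_census(short_traj, short_traj_labels, 0, r_shell=0.0)


class TestDetectBinding:
    def _census(self, n_ice, dt=1.0):
        n_ice = np.asarray(n_ice)
        return ta.SolvationCensus(np.arange(len(n_ice)) * dt,
                                  np.zeros(len(n_ice), int), n_ice, 5.4)

    def test_never_binding_returns_none(self):
        assert ta.detect_binding(self._census([0] * 30)) is None

    def test_bound_from_frame_zero(self):
        assert ta.detect_binding(self._census([9] * 30)) == 0.0

    def test_earliest_sustained_run_wins(self):
        n = [0] * 10 + [5, 5, 0] + [6] * 20
        assert ta.detect_binding(self._census(n), k_ice=4, dwell=5.0) == 13.0

    def test_short_blip_not_reported(self):
        n = [0] * 10 + [6] * 3 + [0] * 20
        assert ta.detect_binding(self._census(n), k_ice=4, dwell=5.0) is None

    def test_scripted_binding_recovered(self, short_traj, short_traj_labels):
        census = ta.solvation_census(
            short_traj, short_traj_labels,
            int(short_traj.metadata["probe_index"]))
        detected = ta.detect_binding(census)
        t_bind = short_traj.metadata["t_bind"]
        dt = short_traj.times[1] - short_traj.times[0]
        assert detected is not None
        assert abs(detected - t_bind) <= 2 * dt


class TestTorsion:
    A = np.array([1.4, 0.0, 1.0])
    B = np.array([0.0, 0.0, 0.0])
    C = np.array([0.0, 0.0, -1.5])

    @pytest.mark.parametrize("target", [0.0, 60.0, -60.0, 120.0, 180.0])
    def test_constructed_geometry_worked_values(self, target):
        d = place_fourth_atom(self.A, self.B, self.C, 1.5, 110.0, target)
        assert dihedral(self.A, self.B, self.C, d) == pytest.approx(target,
                                                                    abs=1e-9)

    def test_sign_matches_mdanalysis_convention(self):
        """Independent oracle for the sign convention."""
        from MDAnalysis.lib.distances import calc_dihedrals
        for target in (60.0, -60.0, 135.0):
            d = place_fourth_atom(self.A, self.B, self.C, 1.5, 110.0, target)
            ref = float(np.degrees(calc_dihedrals(
                self.A[None], self.B[None], self.C[None], d[None]))[0])
            assert dihedral(self.A, self.B, self.C, d) == pytest.approx(
                ref, abs=1e-6)

    def test_collinear_atoms_are_nan(self):
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]] * 6,
                          dtype=float)
        fr = _frameset(coords, ["A", "B", "C", "D"])
        ts = ta.torsion_series(fr, (0, 1, 2, 3), smooth_window=1)
        assert np.isnan(ts.phi).all()

    def test_rotation_translation_invariance(self, rng):
        quad = rng.normal(size=(4, 3)) * 3.0
        rot = Rotation.from_rotvec([0.3, -1.0, 0.7])
        moved = rot.apply(quad) + np.array([5.0, -2.0, 9.0])
        assert dihedral(*quad) == pytest.approx(dihedral(*moved), abs=1e-9)

    def test_moving_average_omits_edges(self):
        coords = np.zeros((20, 4, 3))
        for f in range(20):
            coords[f] = [[1.4, 0, 1], [0, 0, 0], [0, 0, -1.5],
                         place_fourth_atom(self.A, self.B, self.C, 1.5, 110.0,
                                           10.0 * f)]
        fr = _frameset(coords, ["A", "B", "C", "D"])
        ts = ta.torsion_series(fr, (0, 1, 2, 3), smooth_window=5)
        assert len(ts.phi_smooth) == 20 - 5 + 1
        assert len(ts.times_smooth) == len(ts.phi_smooth)

    def test_window_longer_than_series_gives_empty_smooth(self):
        coords = np.random.default_rng(0).normal(size=(10, 4, 3))
        fr = _frameset(coords, ["A", "B", "C", "D"])
        with pytest.warns(UserWarning, match="window"):
            ts = ta.torsion_series(fr, (0, 1, 2, 3), smooth_window=5000)
        assert len(ts.phi_smooth) == 0


class TestPhiHydrationMap:
    def test_total_mass_is_one(self, short_traj, short_traj_labels):
        probe = int(short_traj.metadata["probe_index"])
        census = ta.solvation_census(short_traj, short_traj_labels, probe)
        torsion = ta.torsion_series(short_traj,
                                    tuple(short_traj.metadata["chain_indices"]),
                                    smooth_window=5)
        m = ta.phi_hydration_map(torsion, census, window="full")
        assert m.mass.sum() == pytest.approx(1.0)

    def test_constant_series_occupies_single_cell(self):
        coords = np.zeros((12, 4, 3))
        d = place_fourth_atom(TestTorsion.A, TestTorsion.B, TestTorsion.C,
                              1.5, 110.0, 45.0)
        for f in range(12):
            coords[f] = [TestTorsion.A, TestTorsion.B, TestTorsion.C, d]
        fr = _frameset(coords, ["A", "B", "C", "D"])
        torsion = ta.torsion_series(fr, (0, 1, 2, 3), smooth_window=1)
        census = ta.SolvationCensus(fr.times, np.full(12, 7), np.zeros(12, int),
                                    5.4)
        m = ta.phi_hydration_map(torsion, census, window="full")
        assert np.count_nonzero(m.mass) == 1

    def test_two_conformer_schedule_gives_bimodal_marginal(self):
        """Segments at φ=-85° (2/3 of frames) and φ=+85° (1/3) produce a
        marginal with those weights."""
        n = 30
        coords = np.zeros((n, 4, 3))
        for f in range(n):
            phi = -85.0 if f < 20 else 85.0
            coords[f] = [TestTorsion.A, TestTorsion.B, TestTorsion.C,
                         place_fourth_atom(TestTorsion.A, TestTorsion.B,
                                           TestTorsion.C, 1.5, 110.0, phi)]
        fr = _frameset(coords, ["A", "B", "C", "D"])
        torsion = ta.torsion_series(fr, (0, 1, 2, 3), smooth_window=1)
        census = ta.SolvationCensus(fr.times, np.full(n, 5), np.zeros(n, int),
                                    5.4)
        m = ta.phi_hydration_map(torsion, census, window="full")
        marginal = m.phi_marginal()
        centers = 0.5 * (m.phi_edges[:-1] + m.phi_edges[1:])
        neg = marginal[centers < 0].sum()
        pos = marginal[centers > 0].sum()
        assert neg == pytest.approx(2 / 3, abs=1e-9)
        assert pos == pytest.approx(1 / 3, abs=1e-9)

    def test_empty_window_is_an_error(self, short_traj, short_traj_labels):
        probe = int(short_traj.metadata["probe_index"])
        census = ta.solvation_census(short_traj, short_traj_labels, probe)
        torsion = ta.torsion_series(short_traj,
                                    tuple(short_traj.metadata["chain_indices"]),
                                    smooth_window=5)
        with pytest.raises(ValueError, match="empty"):
            ta.phi_hydration_map(torsion, census, window=(-10.0, -5.0))


class TestHydrogenBonds:
    def _system(self, acceptor, hydrogen):
        # donor O at origin with its H, acceptor water O somewhere
        coords = np.array([[[0, 0, 0], hydrogen, acceptor]], dtype=float)
        fr = _frameset(coords, ["O_DONOR", "H_DONOR", "OW"])
        labels = classify_frameset(fr)
        return fr, labels

    def test_good_geometry_counts_one(self):
        h = [0.957 * np.sin(np.radians(5.0)), 0.0, 0.957 * np.cos(np.radians(5.0))]
        fr, labels = self._system([0, 0, 2.8], h)
        df = ta.hydrogen_bonds(fr, labels, [(0, 1)])
        assert int(df["n_to_ice"].sum() + df["n_to_liquid"].sum()) == 1

    def test_distance_beyond_cutoff_counts_zero(self):
        fr, labels = self._system([0, 0, 4.0], [0, 0, 0.957])
        df = ta.hydrogen_bonds(fr, labels, [(0, 1)])
        assert int(df["n_to_ice"].sum() + df["n_to_liquid"].sum()) == 0

    def test_bent_angle_counts_zero(self):
        h = [0.957 * np.sin(np.radians(60.0)), 0.0,
             0.957 * np.cos(np.radians(60.0))]
        fr, labels = self._system([0, 0, 2.8], h)
        df = ta.hydrogen_bonds(fr, labels, [(0, 1)])
        assert int(df["n_to_ice"].sum() + df["n_to_liquid"].sum()) == 0

    def test_missing_hydrogen_names_the_donor(self):
        fr, labels = self._system([0, 0, 2.8], [0, 0, 0.957])
        with pytest.raises(ValueError, match="donor atom 0"):
            ta.hydrogen_bonds(fr, labels, [(0, 2)])   # index 2 is not an H

    def test_truth_table_via_criterion_function(self):
        assert ta.hydrogen_bond_present([0, 0, 0], [0, 0, 0.96], [0, 0, 2.8])
        assert not ta.hydrogen_bond_present([0, 0, 0], [0, 0, 0.96], [0, 0, 4.0])
        assert not ta.hydrogen_bond_present(
            [0, 0, 0], [0.83, 0, 0.48], [0, 0, 2.8])   # 60° off axis


class TestResiduePairPdf:
    def test_density_integrates_to_one(self, short_traj):
        probe = int(short_traj.metadata["probe_index"])
        chain = short_traj.metadata["chain_indices"]
        edges, density = ta.residue_pair_pdf(short_traj, (probe, chain[-1]))
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_rigid_pair_concentrates_in_one_bin(self):
        coords = np.zeros((25, 2, 3))
        coords[:, 1, 2] = 4.8
        fr = _frameset(coords, ["A", "B"])
        edges, density = ta.residue_pair_pdf(fr, (0, 1), bin_width=0.2)
        occupied = density > 0
        assert occupied.sum() == 1
        left = edges[:-1][occupied][0]
        assert left <= 4.8 <= left + 0.2

    def test_two_state_distance_masses(self):
        """30% of frames at 5 Å, 70% at 9 Å → bin masses 0.3/0.7."""
        n = 40
        coords = np.zeros((n, 2, 3))
        coords[:12, 1, 2] = 5.0
        coords[12:, 1, 2] = 9.0
        fr = _frameset(coords, ["A", "B"])
        edges, density = ta.residue_pair_pdf(fr, (0, 1), bin_width=0.2)
        mass = density * np.diff(edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert mass[np.abs(centers - 5.0) < 0.3].sum() == pytest.approx(0.3)
        assert mass[np.abs(centers - 9.0) < 0.3].sum() == pytest.approx(0.7)


class TestRmsd:
    def test_frame_vs_itself_is_zero(self, short_traj):
        sel = np.array([int(short_traj.metadata["probe_index"])]
                       + list(short_traj.metadata["chain_indices"]))
        series = ta.rmsd_series(short_traj, sel, reference_frame=0,
                                superpose=True)
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_superposes_to_zero(self, rng):
        base = rng.normal(size=(10, 3)) * 4.0
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5])
        moved = rot.apply(base) + np.array([3.0, 4.0, 5.0])
        coords = np.stack([base, moved])
        fr = _frameset(coords, [f"A{i}" for i in range(10)])
        series = ta.rmsd_series(fr, np.arange(10), superpose=True)
        assert series[1] <= 1e-6

    def test_single_displacement_without_superposition(self):
        n, delta = 8, 0.9
        base = np.zeros((n, 3))
        base[:, 0] = np.arange(n) * 3.0
        moved = base.copy()
        moved[3, 2] += delta
        fr = _frameset(np.stack([base, moved]), [f"A{i}" for i in range(n)])
        series = ta.rmsd_series(fr, np.arange(n), superpose=False)
        assert series[1] == pytest.approx(delta / np.sqrt(n))

    def test_superpose_needs_three_atoms(self, short_traj):
        with pytest.raises(ValueError):
            ta.rmsd_series(short_traj, np.array([0, 1]), superpose=True)

    def test_mirror_image_is_not_matched(self, rng):
        base = rng.normal(size=(12, 3)) * 3.0
        mirrored = base * np.array([1.0, 1.0, -1.0])
        _, val = superpose(mirrored, base)
        assert val > 0.1
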