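"""Gating observables: twist, overlap, contacts, salt bridges, BSA, shifts."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from formincg import analysis, synth, tables
from formincg.structure import AtomicStructure, Trajectory


def ca_structure(coords, chain="A", role="A1", resnames=None, atom_names=None,
                 res_ids=None, elements=None):
    n = len(coords)
    return AtomicStructure(
        atom_name=np.array(atom_names if atom_names is not None else ["CA"] * n, dtype="U4"),
        element=np.array(elements if elements is not None else ["C"] * n, dtype="U2"),
        res_name=np.array(resnames if resnames is not None else ["GLY"] * n, dtype="U4"),
        res_id=np.array(res_ids if res_ids is not None else np.arange(1, n + 1)),
        chain_id=np.full(n, chain, dtype="U4"),
        coords=np.asarray(coords, float), roles={chain: role})


class TestTwist:
    def test_pure_translation_reports_zero(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 10, (8, 3))
        assert analysis.twist_angle(a, a + [5.0, -3.0, 2.0]) == pytest.approx(0.0, abs=1e-9)

    def test_ideal_filament_measures_167(self, ideal_seven_mer):
        a1 = ideal_seven_mer.select(role="A1", atoms="calpha").coords
        a2 = ideal_seven_mer.select(role="A2", atoms="calpha").coords
        assert analysis.twist_angle(a1, a2) == pytest.approx(167.0, abs=1e-6)

    def test_matches_quaternion_oracle_at_173_9(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 10, (12, 3))
        axis = np.array([0.2, -0.5, 0.84])
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(173.9) * axis)
        b = R.apply(a) + [1.0, 2.0, 3.0]
        got = analysis.twist_angle(a, b)
        oracle = np.degrees(R.magnitude())
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(173.9, abs=1e-9)

    def test_mismatched_correspondence_rejected(self, ideal_seven_mer):
        short = ideal_seven_mer.select(role="A1", atoms="calpha").coords[:5]
        full = ideal_seven_mer.select(role="A2", atoms="calpha").coords
        with pytest.raises(ValueError):
            analysis.twist_angle(short, full)


class TestTwistStats:
    def test_constant_series(self):
        df = pd.DataFrame({"time_ns": [0, 1, 2], "twist_A1-A2": [167.2] * 3})
        st = analysis.twist_stats(df, "twist_A1-A2")
        assert st["mean"] == 167.2 and st["sd"] == 0.0

    def test_two_point_population_sd(self):
        df = pd.DataFrame({"time_ns": [0, 1], "a": [169.0, 171.0]})
        st = analysis.twist_stats(df, "a")
        assert st["mean"] == 170.0 and st["sd"] == 1.0

    def test_mode_half_degree_bins_tie_to_lower(self):
        vals = [167.1, 167.2, 167.6, 167.7]  # bins [167,167.5) and [167.5,168) tie
        df = pd.DataFrame({"time_ns": range(4), "a": vals})
        st = analysis.twist_stats(df, "a")
        assert st["mode"] == pytest.approx(167.25)

    def test_windowing_and_empty_window(self):
        df = pd.DataFrame({"time_ns": np.linspace(0, 10, 11), "a": np.arange(11.0)})
        st = analysis.twist_stats(df, "a", window=(5.0, 10.0))
        assert st["mean"] == pytest.approx(7.5)
        with pytest.raises(ValueError):
            analysis.twist_stats(df, "a", window=(20.0, 30.0))

    def test_synthetic_series_recovers_configured_mean(self):
        df = synth.synthesize_twist_series(170.2, 0.5, duration_ns=50.0,
                                           dt_ps=40.0, seed=8)
        df = df.rename(columns={"angle_deg": "a"})
        st = analysis.twist_stats(df, "a", window=(0.0, 50.0))
        assert st["mean"] == pytest.approx(170.2, abs=0.1)

    def test_twist_series_on_filament_trajectory(self, ideal_seven_mer):
        frames = np.stack([ideal_seven_mer.coords] * 3)
        traj = Trajectory(frames=frames, dt=40.0)
        df = analysis.twist_series(traj, ideal_seven_mer)
        assert "twist_A1-A2" in df.columns and len(df) == 3
        np.testing.assert_allclose(df["twist_A2-A3"], 167.0, atol=1e-6)


class TestOverlap:
    def test_separated_groups_zero(self):
        a = np.zeros((5, 3))
        b = np.zeros((5, 3)) + [100.0, 0, 0]
        assert analysis.steric_overlap_fraction(a, b) == 0.0

    def test_coincident_groups_one(self):
        a = np.random.default_rng(0).uniform(0, 10, (7, 3))
        assert analysis.steric_overlap_fraction(a, a.copy()) == 1.0

    def test_three_of_ten_clash_matches_brute_force(self):
        target = np.column_stack([np.arange(10) * 10.0, np.zeros(10), np.zeros(10)])
        blocker = target[:3] + [0.0, 3.0, 0.0]  # within 4 A of first three only
        frac = analysis.steric_overlap_fraction(blocker, target)
        assert frac == pytest.approx(0.3)
        brute = np.mean((cdist(target, blocker) < 4.0).any(axis=1))
        assert frac == brute

    def test_strict_inequality_at_threshold(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[4.0, 0, 0]])
        assert analysis.steric_overlap_fraction(a, b, threshold=4.0) == 0.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            analysis.steric_overlap_fraction(np.zeros((2, 3)), np.zeros((0, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_equal_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(10, 250, size=2)
        a = rng.uniform(0, 40, (na, 3))
        b = rng.uniform(0, 40, (nb, 3))
        frac = analysis.steric_overlap_fraction(a, b)
        brute = np.mean((cdist(b, a) < 4.0).any(axis=1))
        assert frac == brute


class TestFractionAbove:
    def test_all_zero(self):
        assert analysis.fraction_frames_above(np.zeros(10)) == 0.0

    def test_half_above(self):
        assert analysis.fraction_frames_above(np.array([0.0, 0.02, 0.05, 0.0])) == 50.0

    def test_exact_threshold_not_counted(self):
        assert analysis.fraction_frames_above(np.array([0.01, 0.02])) == 50.0


class TestContacts:
    def _pair_traj(self, distance):
        s = ca_structure([[0.0, 0, 0], [distance, 0, 0]])
        traj = Trajectory(frames=s.coords[None].repeat(3, axis=0), dt=1.0)
        a = s.select(residues=(1, 1))
        b = s.select(residues=(2, 2))
        return traj, a, b

    @pytest.mark.parametrize("d,expected", [(11.9, 1.0), (12.0, 1.0), (12.1, 0.0)])
    def test_inclusive_boundary(self, d, expected):
        traj, a, b = self._pair_traj(d)
        table = analysis.contact_counts(traj, a, b)
        assert table["contact"].iloc[0] == expected

    def test_random_configuration_equals_double_loop(self):
        rng = np.random.default_rng(3)
        s = ca_structure(rng.uniform(0, 30, (40, 3)))
        traj = Trajectory(frames=s.coords[None], dt=1.0)
        a = s.select(residues=(1, 20))
        b = s.select(residues=(21, 40))
        table = analysis.contact_counts(traj, a, b)
        got = table["contact"].to_numpy().reshape(20, 20)
        brute = (cdist(s.coords[:20], s.coords[20:]) <= 12.0).astype(float)
        np.testing.assert_array_equal(got, brute)

    def test_empty_window_rejected(self):
        traj, a, b = self._pair_traj(5.0)
        with pytest.raises(ValueError):
            analysis.contact_counts(traj, a, b, window=(99.0, 100.0))


class TestSaltBridges:
    def _bridge_system(self, d_frame2):
        coords = [[0.0, 0, 0], [3.5, 0, 0]]
        s = ca_structure(coords, resnames=["LYS", "ASP"],
                         atom_names=["NZ", "OD1"], elements=["N", "O"])
        f1 = np.array(coords)
        f2 = np.array([[0.0, 0, 0], [d_frame2, 0, 0]])
        traj = Trajectory(frames=np.stack([f1, f2]), dt=1.0)
        a = s.select(residues=(1, 1))
        b = s.select(residues=(2, 2))
        return traj, a, b

    def test_half_occupancy(self):
        traj, a, b = self._bridge_system(10.0)
        table = analysis.salt_bridge_occupancy(traj, a, b)
        assert table["occupancy"].iloc[0] == 50.0

    def test_exact_four_angstrom_counted(self):
        traj, a, b = self._bridge_system(4.0)
        table = analysis.salt_bridge_occupancy(traj, a, b)
        assert table["occupancy"].iloc[0] == 100.0

    def test_no_charged_residues_empty(self):
        s = ca_structure([[0.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(frames=s.coords[None], dt=1.0)
        table = analysis.salt_bridge_occupancy(traj, s.select(residues=(1, 1)),
                                               s.select(residues=(2, 2)))
        assert table.empty

    def test_his_counted_only_when_protonated(self):
        s = ca_structure([[0.0, 0, 0], [3.0, 0, 0]], resnames=["HIS", "GLU"],
                         atom_names=["NE2", "OE1"], elements=["N", "O"])
        traj = Trajectory(frames=s.coords[None], dt=1.0)
        a, b = s.select(residues=(1, 1)), s.select(residues=(2, 2))
        assert analysis.salt_bridge_occupancy(traj, a, b).empty
        table = analysis.salt_bridge_occupancy(traj, a, b, protonated_his=True)
        assert table["occupancy"].iloc[0] == 100.0


class TestBridgeCounts:
    def test_published_five_mer_knob_groove_counts(self):
        table = tables.load_salt_bridge_table("knob_groove_salt_bridges")
        col = "occupancy_C_5mer_350ns"
        assert tables.count_bridges(table, "Cdc12", col) == 9
        assert tables.count_bridges(table, "Bni1", col) == 2
        assert tables.count_bridges(table, "mDia1", col) == 1

    def test_empty_table_zero(self):
        empty = tables.load_salt_bridge_table("knob_groove_salt_bridges").iloc[0:0]
        assert tables.count_bridges(empty, occupancy_column="occupancy_C_5mer_350ns") == 0

    def test_min_occupancy_70_matches_manual_tally(self):
        table = tables.load_salt_bridge_table("knob_groove_salt_bridges")
        col = "occupancy_A_7mer_200ns"
        # manual count of printed rows >= 70%: K1068/FHL 78.2, E1093/FHL 99.4,
        # K1068/FHT 95.2, E1093/FHT 94.8
        assert tables.count_bridges(table, "Cdc12", col, min_occupancy=70.0) == 4

    def test_lasso_linker_table_d363_row(self):
        table = tables.load_salt_bridge_table("lasso_linker_salt_bridges")
        d363 = table[(table["actin_residue"] == "D363") &
                     (table["fh2_domain"].str.contains("lasso")) &
                     (table["actin_subunit"] == "A2")]
        occ = dict(zip(d363["formin"], d363["occupancy_7mer_200ns"]))
        assert occ == {"Cdc12": 100.0, "Bni1": 85.2, "mDia1": 23.4}


class TestBuriedSurface:
    def test_far_groups_zero_within_quadrature_noise(self):
        s = ca_structure([[0.0, 0, 0], [100.0, 0, 0]])
        a = s.select(residues=(1, 1))
        b = s.select(residues=(2, 2))
        assert abs(analysis.buried_surface_area(s, a, b)) < 1.0

    def test_single_sphere_analytic_area(self):
        s = ca_structure([[0.0, 0, 0]])
        area = analysis.sasa(s)
        r = 1.7 + 1.4
        assert area == pytest.approx(4 * np.pi * r * r, rel=0.01)

    def test_two_sphere_overlap_matches_spherical_caps(self):
        """BSA of two identical spheres vs the analytic lens formula: each
        solvent-expanded sphere of radius R loses a cap of height h =
        R - d/2, area 2 pi R h; BSA counts both faces."""
        d = 4.0
        s = ca_structure([[0.0, 0, 0], [d, 0, 0]])
        a = s.select(residues=(1, 1))
        b = s.select(residues=(2, 2))
        bsa = analysis.buried_surface_area(s, a, b)
        R = 1.7 + 1.4
        h = R - d / 2.0
        analytic = 2 * (2 * np.pi * R * h)
        assert bsa == pytest.approx(analytic, rel=0.02)

    def test_symmetric_in_groups(self, demo_complex):
        a = demo_complex.select(role="FHL")
        b = demo_complex.select(role="A2")
        ab = analysis.buried_surface_area(demo_complex, a, b)
        ba = analysis.buried_surface_area(demo_complex, b, a)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab >= -1.0


class TestRmsdRmsf:
    def test_identical_frames_zero(self, ideal_seven_mer):
        frames = np.stack([ideal_seven_mer.coords] * 4)
        traj = Trajectory(frames=frames, dt=1.0)
        g = ideal_seven_mer.select(role="A1")
        rmsd, rmsf = analysis.rmsd_rmsf(traj, g)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-9)
        np.testing.assert_allclose(rmsf, 0.0, atol=1e-9)

    def test_rigid_rotation_zero_after_alignment(self, ideal_seven_mer):
        R = Rotation.from_rotvec([0.4, 0.1, -0.3]).as_matrix()
        frames = np.stack([ideal_seven_mer.coords,
                           ideal_seven_mer.coords @ R.T + [10.0, 0, 0]])
        traj = Trajectory(frames=frames, dt=1.0)
        g = ideal_seven_mer.select(role="A1")
        rmsd, _ = analysis.rmsd_rmsf(traj, g)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-8)

    def test_single_atom_displacement_formula(self):
        n = 25
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 20, (n, 3))
        moved = base.copy()
        moved[0, 0] += 1.0
        s = ca_structure(base)
        traj = Trajectory(frames=np.stack([base, moved]), dt=1.0)
        rmsd, _ = analysis.rmsd_rmsf(traj, s.select(), align=False)
        assert rmsd[1] == pytest.approx(1.0 / np.sqrt(n), rel=1e-9)


class TestRadialShift:
    def test_static_group_zero(self, ideal_seven_mer):
        frames = np.stack([ideal_seven_mer.coords] * 3)
        traj = Trajectory(frames=frames, dt=1.0)
        g = ideal_seven_mer.select(role="A1")
        point, axis = analysis.filament_axis(ideal_seven_mer)
        df = analysis.com_radial_shift_percent(traj, g, point, axis)
        np.testing.assert_allclose(df["radial_shift_percent"], 0.0, atol=1e-9)

    def test_thirty_to_twentyseven_is_plus_ten_percent(self):
        s = ca_structure([[30.0, 0, 0]])
        frames = np.array([[[30.0, 0, 0]], [[27.0, 0, 0]]])
        traj = Trajectory(frames=frames, dt=1.0)
        df = analysis.com_radial_shift_percent(traj, s.select(), [0, 0, 0], [0, 0, 1])
        assert df["radial_shift_percent"].iloc[1] == pytest.approx(10.0)

    def test_axial_motion_invisible(self):
        s = ca_structure([[30.0, 0, 0]])
        frames = np.array([[[30.0, 0, 0]], [[30.0, 0, 50.0]]])
        traj = Trajectory(frames=frames, dt=1.0)
        df = analysis.com_radial_shift_percent(traj, s.select(), [0, 0, 0], [0, 0, 1])
        assert df["radial_shift_percent"].iloc[1] == pytest.approx(0.0, abs=1e-9)


class TestIncomingSubunit:
    def test_placement_closure_against_longer_filament(self, bent_rod):
        """Removing A1 from an 8-mer and placing the incoming subunit on the
        remaining 7-mer regenerates the removed subunit exactly."""
        geom = synth.HelixGeometry(twist_deg=167.0)
        fil8 = synth.build_ideal_filament(bent_rod, 8, geom)
        removed_a1 = fil8.select(role="A1", atoms="calpha").coords
        seven = fil8.copy()
        chains = fil8.chains()
        # subunits keep their names after A1 removal: the end is now A2
        seven.roles = {c: f"A{i}" for i, c in enumerate(chains[1:], start=2)}
        placed = analysis.place_incoming_subunit(seven, 167.0, geom.rise)
        rmsd = np.sqrt(np.mean(np.sum((placed - removed_a1) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_round_trip_interface_twist(self, ideal_seven_mer):
        placed = analysis.place_incoming_subunit(ideal_seven_mer, 167.0,
                                                 synth.DEFAULT_RISE)
        a2 = ideal_seven_mer.select(role="A2", atoms="calpha").coords
        assert analysis.twist_angle(placed, a2) == pytest.approx(167.0, abs=1e-6)

    def test_flattened_end_misplaces_ideal_geometry(self, bent_rod):
        flat = synth.build_flattened_filament(bent_rod, 6,
                                              [175.0, 167.0, 167.0, 167.0, 167.0])
        flat.roles = {c: f"A{i + 1}" for i, c in enumerate(flat.chains())}
        ideal_placed = analysis.place_incoming_subunit(flat, 167.0, synth.DEFAULT_RISE)
        true_a1 = flat.select(role="A1", atoms="calpha").coords
        # the existing end subunit sits at a 175 deg interface; the ideal
        # 167 deg placement lands measurably elsewhere
        mismatch = np.sqrt(np.mean(np.sum((ideal_placed - true_a1) ** 2, axis=1)))
        assert mismatch > 1.0


def test_filament_axis_of_ideal_filament_is_helix_axis(ideal_seven_mer):
    point, axis = analysis.filament_axis(ideal_seven_mer)
    assert abs(axis @ np.array([0.0, 0, 1.0])) == pytest.approx(1.0, abs=1e-6)
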