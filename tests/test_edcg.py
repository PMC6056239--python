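"""ED-CG: essential modes, exact DP partitioning, trajectory mapping."""

import itertools

import numpy as np
import pytest

from formincg import edcg
from formincg.structure import AtomicStructure, Trajectory


def make_structure(n_res, chain="A", resnames=None):
    if resnames is None:
        resnames = ["GLY"] * n_res
    rng = np.random.default_rng(0)
    return AtomicStructure(
        atom_name=np.full(n_res, "CA", dtype="U4"),
        element=np.full(n_res, "C", dtype="U2"),
        res_name=np.array(resnames, dtype="U4"),
        res_id=np.arange(1, n_res + 1),
        chain_id=np.full(n_res, chain, dtype="U4"),
        coords=rng.uniform(0, 20, (n_res, 3)),
        roles={chain: "A1"},
    )


def random_trajectory(n_res, n_frames, seed, scale=0.5):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 30, (n_res, 3))
    frames = base + rng.normal(scale=scale, size=(n_frames, n_res, 3))
    return Trajectory(frames=frames, dt=1.0)


def brute_force_partition(modes, n_res, n_sites):
    """Exhaustive enumeration over all contiguous partitions (oracle)."""
    T = modes.essential_covariance_blocks()
    d = np.diag(T)
    M = d[:, None] + d[None, :] - 2 * T

    def chi2_of(bounds):
        total = 0.0
        lo = 0
        for b in list(bounds) + [n_res - 1]:
            idx = range(lo, b + 1)
            n_I = b + 1 - lo
            s = sum(M[i, j] for i, j in itertools.combinations(idx, 2))
            total += s / n_I
            lo = b + 1
        return total / (3 * n_res)

    best = None
    for bounds in itertools.combinations(range(n_res - 1), n_sites - 1):
        c = chi2_of(bounds)
        if best is None or c < best[0] - 1e-12:
            best = (c, bounds)
    return best


class TestEssentialModes:
    def test_single_direction_motion_captured_by_one_mode(self):
        base = np.random.default_rng(1).uniform(0, 10, (6, 3))
        direction = np.zeros((6, 3))
        direction[0, 0] = 1.0  # internal stretch of one residue
        amps = np.linspace(-1, 1, 50)
        frames = base + amps[:, None, None] * direction
        traj = Trajectory(frames=frames, dt=1.0)
        modes = edcg.essential_modes(traj, n_modes=1, n_align_passes=0)
        assert modes.variances[0] / modes.total_variance == pytest.approx(1.0, abs=1e-10)

    def test_all_modes_reconstruct_displacements(self):
        traj = random_trajectory(5, 40, seed=2)
        modes = edcg.essential_modes(traj, n_modes=15, n_align_passes=0)
        flat = traj.frames.reshape(40, -1) - modes.mean
        recon = (flat @ modes.modes.T) @ modes.modes
        np.testing.assert_allclose(recon, flat, atol=1e-8)

    def test_modes_orthonormal_variances_sorted(self):
        traj = random_trajectory(8, 60, seed=3)
        modes = edcg.essential_modes(traj)
        gram = modes.modes @ modes.modes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        assert np.all(np.diff(modes.variances) <= 1e-12)

    def test_too_few_frames_rejected(self):
        traj = random_trajectory(5, 2, seed=0)
        with pytest.raises(ValueError):
            edcg.essential_modes(traj, n_modes=5)

    def test_isotropic_noise_eigenvalues_flat(self):
        """i.i.d. isotropic noise: eigenvalue spread stays within the spread
        of shuffled (null) data, a Monte-Carlo flatness check."""
        rng = np.random.default_rng(4)
        n_frames, n_res = 400, 6
        frames = rng.normal(size=(n_frames, n_res, 3))
        traj = Trajectory(frames=frames, dt=1.0)
        modes = edcg.essential_modes(traj, n_modes=3 * n_res, n_align_passes=0)
        shuffled = frames.reshape(n_frames, -1).copy()
        for col in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, col])
        null = edcg.essential_modes(
            Trajectory(frames=shuffled.reshape(n_frames, n_res, 3), dt=1.0),
            n_modes=3 * n_res, n_align_passes=0)
        spread = modes.variances[0] / modes.variances[-1]
        null_spread = null.variances[0] / null.variances[-1]
        assert spread < 2.0 * null_spread


class TestPartition:
    def test_hinge_boundary_found_exactly(self):
        # two compact bodies far from the central joint: the right body
        # librates about the joint, so its residues share one displacement
        # field distinct from the static left body
        rng = np.random.default_rng(5)
        left = np.column_stack([np.linspace(-10, -8, 10), np.zeros(10), rng.uniform(0, 2, 10)])
        right = np.column_stack([np.linspace(8, 10, 10), np.zeros(10), rng.uniform(0, 2, 10)])
        frames = []
        for ang in rng.normal(scale=0.15, size=60):
            c, s = np.cos(ang), np.sin(ang)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            frames.append(np.vstack([left, right @ R.T]))
        traj = Trajectory(frames=np.array(frames), dt=1.0)
        modes = edcg.essential_modes(traj, n_modes=1, n_align_passes=0)
        res = edcg.edcg_partition(modes, range(1, 21), 2)
        assert res.mapping.segments == [("A", 1, 10, 0), ("A", 11, 20, 1)]
        _, bounds = brute_force_partition(modes, 20, 2)
        assert bounds == (9,)

    def test_one_site_per_residue_zero_residual(self):
        traj = random_trajectory(6, 30, seed=6)
        modes = edcg.essential_modes(traj, n_modes=3)
        res = edcg.edcg_partition(modes, range(1, 7), 6)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_zero_everywhere_leftmost_tiebreak(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 10, (8, 3))
        shifts = rng.normal(scale=1.0, size=(40, 1, 3))
        traj = Trajectory(frames=base + shifts, dt=1.0)
        modes = edcg.essential_modes(traj, n_modes=3, n_align_passes=0)
        res = edcg.edcg_partition(modes, range(1, 9), 3)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        # lexicographically smallest boundary vector: earliest possible cuts
        assert res.mapping.segments == [("A", 1, 1, 0), ("A", 2, 2, 1), ("A", 3, 8, 2)]

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_res = int(rng.integers(6, 21))
        n_sites = int(rng.integers(2, 5))
        traj = random_trajectory(n_res, 50, seed=seed + 100)
        modes = edcg.essential_modes(traj, n_modes=4, n_align_passes=0)
        res = edcg.edcg_partition(modes, range(1, n_res + 1), n_sites)
        chi2_bf, bounds_bf = brute_force_partition(modes, n_res, n_sites)
        assert res.chi2 == pytest.approx(chi2_bf, rel=1e-9, abs=1e-12)
        got_bounds = tuple(hi - 1 for _, _, hi, _ in res.mapping.segments[:-1])
        assert got_bounds == bounds_bf

    def test_chi2_non_increasing_in_site_count(self):
        traj = random_trajectory(12, 60, seed=9)
        modes = edcg.essential_modes(traj, n_modes=5, n_align_passes=0)
        chis = [edcg.edcg_partition(modes, range(1, 13), k).chi2
                for k in range(1, 7)]
        assert all(a >= b - 1e-12 for a, b in zip(chis, chis[1:]))

    def test_partition_invariant_to_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        traj = random_trajectory(10, 50, seed=10)
        rng = np.random.default_rng(11)
        frames = traj.frames.copy()
        for f in range(frames.shape[0]):
            R = Rotation.from_rotvec(rng.normal(scale=0.3, size=3)).as_matrix()
            frames[f] = frames[f] @ R.T + rng.normal(scale=2.0, size=3)
        moved = Trajectory(frames=frames, dt=1.0)
        res_a = edcg.edcg_partition(edcg.essential_modes(traj, n_modes=3),
                                    range(1, 11), 3)
        res_b = edcg.edcg_partition(edcg.essential_modes(moved, n_modes=3),
                                    range(1, 11), 3)
        assert res_a.mapping.segments == res_b.mapping.segments

    def test_too_many_sites_rejected(self):
        traj = random_trajectory(5, 20, seed=12)
        modes = edcg.essential_modes(traj, n_modes=2)
        with pytest.raises(ValueError):
            edcg.edcg_partition(modes, range(1, 6), 6)


class TestMapTrajectory:
    def test_one_site_per_chain_is_com(self):
        s = make_structure(4)
        mapping = edcg.CGMapping(segments=[("A", 1, 4, 0)])
        frames = np.stack([s.coords, s.coords + 2.0])
        traj = Trajectory(frames=frames, dt=1.0)
        cg = edcg.map_trajectory(traj, mapping, structure=s, weights="uniform")
        np.testing.assert_allclose(cg.frames[0, 0], s.coords.mean(axis=0))
        np.testing.assert_allclose(cg.frames[1, 0], s.coords.mean(axis=0) + 2.0)

    def test_uniform_weights_midpoint(self):
        s = make_structure(2)
        s.coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        mapping = edcg.CGMapping(segments=[("A", 1, 2, 0)])
        traj = Trajectory(frames=s.coords[None], dt=1.0)
        cg = edcg.map_trajectory(traj, mapping, structure=s, weights="uniform")
        np.testing.assert_allclose(cg.frames[0, 0], [1.0, 0, 0])

    def test_mass_weights_three_to_one(self):
        # TRP (186.21) vs GLY (57.05) is not 3:1; use explicit masses via
        # residue names GLY + a hypothetical triple-mass: emulate with TRP?
        # Instead check against the hand-computed weighted centroid.
        s = make_structure(2, resnames=["GLY", "TRP"])
        s.coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        mapping = edcg.CGMapping(segments=[("A", 1, 2, 0)])
        traj = Trajectory(frames=s.coords[None], dt=1.0)
        cg = edcg.map_trajectory(traj, mapping, structure=s, weights="mass")
        from formincg.constants import RESIDUE_MASSES
        expected = 4.0 * RESIDUE_MASSES["TRP"] / (RESIDUE_MASSES["TRP"] +
                                                  RESIDUE_MASSES["GLY"])
        np.testing.assert_allclose(cg.frames[0, 0], [expected, 0, 0])

    def test_mapping_round_trips_through_file(self, tmp_path):
        mapping = edcg.CGMapping(segments=[("A", 1, 10, 0), ("A", 11, 20, 1)],
                                 mass=np.array([100.0, 120.0]),
                                 charge=np.array([1.0, -1.0]),
                                 sigma=np.array([3.0, 4.0]))
        p = tmp_path / "map.tsv"
        mapping.save(p)
        back = edcg.CGMapping.load(p)
        assert [tuple(s) for s in back.segments] == mapping.segments
        np.testing.assert_allclose(back.charge, mapping.charge)
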