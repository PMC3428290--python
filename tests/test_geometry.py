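import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import duplexmd as dm
from duplexmd.geometry import DegenerateGeometryError
from conftest import apply_rigid, random_rigid_motion

from _oracles import brute_force_superposed_rmsd


def _points(n, seed):
    return np.random.default_rng(seed).uniform(-4, 4, size=(n, 3))


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self):
        pts = _points(5, 1)
        res = dm.kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_is_fully_recovered(self):
        pts = _points(6, 2)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = apply_rigid(pts, R, np.array([5.0, 0.0, 0.0]))
        res = dm.kabsch(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.apply(moved), pts, atol=1e-9)

    def test_rotation_is_always_proper(self):
        # near-planar sets are where an unconstrained fit would reflect
        pts = _points(5, 3)
        pts[:, 2] *= 1e-3
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        res = dm.kabsch(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        pts = rng.uniform(-3, 3, size=(n, 3))
        noisy = pts + rng.normal(0, 0.4, size=pts.shape)
        R, t = random_rigid_motion(rng)
        mobile = apply_rigid(noisy, R, t)
        assert dm.kabsch(mobile, pts).rmsd == pytest.approx(
            brute_force_superposed_rmsd(mobile, pts), abs=1e-3)

    def test_count_mismatch_and_degenerate_inputs_rejected(self):
        pts = _points(5, 4)
        with pytest.raises(ValueError):
            dm.kabsch(pts, pts[:4])
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            dm.kabsch(line + 0.0, line)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, duplex):
        traj = dm.Trajectory(duplex.topology, np.repeat(duplex.coords, 5, axis=0), dt=10)
        ds = dm.rmsd_series(traj, duplex.coords[0], dm.Selection(names="C5'"))
        np.testing.assert_allclose(ds.values, 0.0, atol=1e-9)

    def test_per_frame_rigid_motion_is_zero(self, duplex):
        rng = np.random.default_rng(5)
        frames = []
        for _ in range(6):
            R, t = random_rigid_motion(rng)
            frames.append(apply_rigid(duplex.coords[0], R, t))
        traj = dm.Trajectory(duplex.topology, np.array(frames), dt=10)
        ds = dm.rmsd_series(traj, duplex.coords[0], dm.Selection(names="C5'"))
        np.testing.assert_allclose(ds.values, 0.0, atol=1e-6)

    def test_matches_independent_per_frame_evaluation(self, jittered_traj):
        """Cross-check each frame's superposed RMSD against MDAnalysis."""
        from MDAnalysis.analysis import rms
        sel = dm.Selection(names="C5'")
        idx = dm.select(jittered_traj.topology, sel)
        ref = jittered_traj.coords[0]
        ds = dm.rmsd_series(jittered_traj, ref, sel)
        for k in (0, 10, 49):
            oracle = rms.rmsd(jittered_traj.coords[k][idx], ref[idx],
                              center=True, superposition=True)
            assert ds.values[k] == pytest.approx(oracle, abs=1e-6)

    def test_empty_selection_rejected(self, jittered_traj):
        with pytest.raises(ValueError, match="selection"):
            dm.rmsd_series(jittered_traj, jittered_traj.coords[0],
                           dm.Selection(chains="Z"))


class TestAverageStructure:
    def test_static_trajectory_returns_that_structure(self, duplex):
        traj = dm.Trajectory(duplex.topology, np.repeat(duplex.coords, 4, axis=0), dt=10)
        sel = dm.Selection(names="C5'")
        idx = dm.select(duplex.topology, sel)
        np.testing.assert_allclose(dm.average_structure(traj, sel),
                                   duplex.coords[0][idx], atol=1e-9)

    def test_two_symmetric_frames_average_to_midpoint(self, duplex):
        sel = dm.Selection(names="C5'")
        idx = dm.select(duplex.topology, sel)
        delta = np.zeros_like(duplex.coords[0])
        delta[idx[0]] = [0.4, 0.0, 0.0]  # one atom displaced symmetrically
        frames = np.array([duplex.coords[0] + delta, duplex.coords[0] - delta])
        traj = dm.Trajectory(duplex.topology, frames, dt=10)
        mean = dm.average_structure(traj, sel)
        # the iterated mean is defined up to a rigid motion of the seed frame
        # and matches the midpoint to second order in the displacement
        assert dm.kabsch(mean, duplex.coords[0][idx]).rmsd < 1e-3

    def test_recovers_generator_mean_under_jitter(self, duplex):
        sigma, n_frames = 0.3, 400
        motion = dm.MotionSpec(n_frames=n_frames, dt=10, jitter_sigma=sigma, seed=2)
        traj = dm.make_trajectory(duplex, motion)
        sel = dm.Selection(names="C5'")
        idx = dm.select(duplex.topology, sel)
        mean = dm.average_structure(traj, sel)
        fitted = dm.superpose(mean, duplex.coords[0][idx])
        err = np.linalg.norm(fitted - duplex.coords[0][idx], axis=1).max()
        assert err < 3 * sigma / np.sqrt(n_frames) * 3  # 3-sigma bound per axis


class TestRmsf:
    def test_static_trajectory_gives_zero(self, duplex):
        traj = dm.Trajectory(duplex.topology, np.repeat(duplex.coords, 4, axis=0), dt=10)
        prof = dm.rmsf(traj, dm.Selection(names="C5'"))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_single_frame_rejected(self, duplex):
        with pytest.raises(ValueError):
            dm.rmsf(duplex, dm.Selection(names="C5'"))

    def test_single_jittered_atom_approaches_sigma_sqrt3(self, duplex):
        # superpose over all atoms so the fit absorbs a negligible share
        sigma, n_frames = 0.25, 3000
        rng = np.random.default_rng(9)
        n_atoms = duplex.topology.n_atoms
        frames = np.repeat(duplex.coords, n_frames, axis=0).copy()
        frames[:, 42, :] += rng.normal(0, sigma, size=(n_frames, 3))
        traj = dm.Trajectory(duplex.topology, frames, dt=10)
        prof = dm.rmsf(traj, dm.Selection())
        assert prof.values[42] == pytest.approx(sigma * np.sqrt(3), rel=0.03)
        assert prof.values[np.arange(n_atoms) != 42].max() < 0.05

    def test_opening_terminal_pairs_fluctuate_more_than_core(self, opening_traj, duplex):
        """Programmed terminal opening raises terminal-nucleotide RMSF above the core."""
        prof = dm.rmsf(opening_traj, dm.Selection(names="C5'"))
        by_key = dict(zip(prof.keys, prof.values))
        # strand-B nucleotides of opening pairs 1-3 are B13, B12, B11
        opening_vals = [by_key[("B", r, "C5'")] for r in (13, 12, 11)]
        core_vals = [by_key[(c, r, "C5'")] for c in ("A", "B") for r in (5, 6, 7)]
        assert min(opening_vals) > max(core_vals)


class TestRgAndCom:
    def test_single_atom_rg_zero(self):
        assert dm.radius_of_gyration(np.zeros((1, 3)), np.array([0])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert dm.radius_of_gyration(frame, np.array([0, 1]),
                                     masses=np.ones(2)) == pytest.approx(1.0)

    def test_matches_direct_formula_on_duplex(self, duplex):
        sel = dm.Selection(names="C5'")
        idx = dm.select(duplex.topology, sel)
        m = duplex.topology.masses[idx]
        X = duplex.coords[0][idx]
        com = (X * m[:, None]).sum(axis=0) / m.sum()
        direct = np.sqrt((m * ((X - com) ** 2).sum(axis=1)).sum() / m.sum())
        assert dm.radius_of_gyration(duplex.coords[0], sel,
                                     topo=duplex.topology) == pytest.approx(direct, abs=1e-9)

    def test_center_of_mass_cases(self):
        assert np.allclose(dm.center_of_mass(np.array([[1.0, 2, 3]])), [1, 2, 3])
        two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert np.allclose(dm.center_of_mass(two, np.ones(2)), [1, 0, 0])
        four = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert np.allclose(dm.center_of_mass(four, np.array([1.0, 3.0])), [3, 0, 0])


class TestInvariances:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rmsd_symmetric_and_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, size=(6, 3))
        b = a + rng.normal(0, 0.5, size=a.shape)
        r_ab = dm.kabsch(a, b).rmsd
        assert dm.kabsch(b, a).rmsd == pytest.approx(r_ab, abs=1e-9)
        R, t = random_rigid_motion(rng)
        assert dm.kabsch(apply_rigid(a, R, t), b).rmsd == pytest.approx(r_ab, abs=1e-8)

    @given(seed=st.integers(0, 2**31 - 1),
           c=st.floats(0.1, 5.0, allow_nan=False))
    @settings(max_examples=15, deadline=None)
    def test_rg_rmsf_rigid_invariance_and_scaling(self, seed, c, duplex):
        rng = np.random.default_rng(seed)
        motion = dm.MotionSpec(n_frames=8, dt=10, jitter_sigma=0.3, seed=seed % 1000)
        traj = dm.make_trajectory(duplex, motion)
        sel = dm.Selection(names="C5'")
        idx = dm.select(traj.topology, sel)
        m = traj.topology.masses[idx]
        rg0 = dm.radius_of_gyration(traj.coords[0], idx, masses=m)
        prof0 = dm.rmsf(traj, sel)
        R, t = random_rigid_motion(rng)
        moved = dm.Trajectory(traj.topology, apply_rigid(traj.coords, R, t), dt=10)
        assert dm.radius_of_gyration(moved.coords[0], idx,
                                     masses=m) == pytest.approx(rg0, abs=1e-9)
        np.testing.assert_allclose(dm.rmsf(moved, sel).values, prof0.values, atol=1e-6)
        scaled = dm.Trajectory(traj.topology, traj.coords * c, dt=10)
        assert dm.radius_of_gyration(scaled.coords[0], idx,
                                     masses=m) == pytest.approx(c * rg0, rel=1e-9)
        np.testing.assert_allclose(dm.rmsf(scaled, sel).values,
                                   c * prof0.values, atol=1e-6 * max(c, 1))
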