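import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ltk.core import Trajectory
from ltk.dynamics import (
    cross_correlation,
    filter_hbonds,
    hbond_occupancy,
    rmsd_series,
    rmsf_difference,
    rmsf_profile,
    superpose,
)
from ltk.synthetic import make_fluctuation_trajectory, make_point_charge_system


def random_trajectory(n_atoms=10, n_frames=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(-5, 5, size=(n_atoms, 3))
    system = make_point_charge_system(base, np.zeros(n_atoms))
    frames = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        rot = Rotation.random(random_state=rng.integers(2**31))
        shift = rng.uniform(-10, 10, size=3)
        frame = rot.apply(base) + shift
        if noise:
            frame = frame + rng.normal(scale=noise, size=frame.shape)
        frames[f] = frame
    frames[0] = base
    return Trajectory(system, frames)


class TestSuperpose:
    def test_rigid_translations_give_zero_rmsd(self):
        traj = random_trajectory(noise=0.0, seed=1)
        # keep only translations: rebuild frames as base + shift
        base = traj.frames[0]
        rng = np.random.default_rng(2)
        frames = base[None] + rng.uniform(-5, 5, size=(4, 1, 3))
        shifted = Trajectory(traj.topology, frames)
        rmsd = rmsd_series(shifted)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-10)

    def test_rigid_rotations_give_zero_rmsd(self):
        traj = random_trajectory(noise=0.0, seed=3)
        rmsd = rmsd_series(traj)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-8)

    def test_matches_quaternion_oracle_on_noisy_frames(self):
        # independent oracle: Horn's quaternion method via the Kearsley
        # matrix eigen-decomposition
        traj = random_trajectory(noise=0.3, seed=4)
        fitted = superpose(traj)
        for f in range(1, traj.n_frames):
            x = traj.frames[0] - traj.frames[0].mean(axis=0)
            y = traj.frames[f] - traj.frames[f].mean(axis=0)
            # Kearsley matrix
            d = y - x
            s = y + x
            K = np.empty((4, 4))
            K[0, 0] = (d**2).sum()
            K[0, 1] = K[1, 0] = np.sum(s[:, 1] * d[:, 2] - d[:, 1] * s[:, 2])
            K[0, 2] = K[2, 0] = np.sum(d[:, 0] * s[:, 2] - s[:, 0] * d[:, 2])
            K[0, 3] = K[3, 0] = np.sum(s[:, 0] * d[:, 1] - d[:, 0] * s[:, 1])
            K[1, 1] = (d[:, 0] ** 2 + s[:, 1] ** 2 + s[:, 2] ** 2).sum()
            K[1, 2] = K[2, 1] = np.sum(d[:, 0] * d[:, 1] - s[:, 0] * s[:, 1])
            K[1, 3] = K[3, 1] = np.sum(d[:, 0] * d[:, 2] - s[:, 0] * s[:, 2])
            K[2, 2] = (s[:, 0] ** 2 + d[:, 1] ** 2 + s[:, 2] ** 2).sum()
            K[2, 3] = K[3, 2] = np.sum(d[:, 1] * d[:, 2] - s[:, 1] * s[:, 2])
            K[3, 3] = (s[:, 0] ** 2 + s[:, 1] ** 2 + d[:, 2] ** 2).sum()
            min_eig = np.linalg.eigvalsh(K)[0]
            oracle_rmsd = np.sqrt(max(min_eig, 0.0) / len(x))
            got = np.sqrt(((fitted.frames[f] - fitted.frames[0]) ** 2).sum(1).mean())
            assert got == pytest.approx(oracle_rmsd, abs=1e-8)

    def test_no_random_rotation_beats_fit(self):
        traj = random_trajectory(noise=0.2, seed=5, n_frames=2)
        fitted = superpose(traj)
        best = np.sqrt(((fitted.frames[1] - fitted.frames[0]) ** 2).sum(1).mean())
        rng = np.random.default_rng(6)
        x = traj.frames[0] - traj.frames[0].mean(axis=0)
        y = traj.frames[1] - traj.frames[1].mean(axis=0)
        for _ in range(2000):
            trial = Rotation.random(random_state=rng.integers(2**31)).apply(y)
            rmsd = np.sqrt(((trial - x) ** 2).sum(1).mean())
            assert rmsd >= best - 1e-9

    def test_collinear_selection_rejected(self):
        positions = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        system = make_point_charge_system(positions, np.zeros(4))
        traj = Trajectory(system, positions[None].repeat(2, axis=0))
        with pytest.raises(ValueError, match="collinear"):
            superpose(traj)


class TestRmsd:
    def test_identical_frame_zero(self):
        traj = random_trajectory(seed=7)
        assert rmsd_series(traj)[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_closed_form(self):
        n = 16
        positions = np.random.default_rng(8).uniform(-5, 5, size=(n, 3))
        system = make_point_charge_system(positions, np.zeros(n))
        frames = positions[None].repeat(2, axis=0).copy()
        frames[1, 0] += [0.9, 0.0, 0.0]
        traj = Trajectory(system, frames)
        # without refitting, RMSD = d / sqrt(n)
        rmsd = rmsd_series(traj, fit=False)
        assert rmsd[1] == pytest.approx(0.9 / np.sqrt(n), rel=1e-10)


class TestRmsf:
    def test_static_atoms_zero(self):
        traj = make_fluctuation_trajectory(
            means=np.ones((3, 3)), stdevs=np.zeros((3, 3)), n_frames=50, seed=0
        )
        profile = rmsf_profile(traj)
        np.testing.assert_allclose(profile.values, 0.0)

    def test_gaussian_ensemble_recovers_stdev(self):
        traj = make_fluctuation_trajectory(
            means=np.zeros((2, 3)),
            stdevs=np.array([[0.3, 0.0, 0.0], [0.1, 0.1, 0.1]]),
            n_frames=10_000,
            seed=9,
        )
        profile = rmsf_profile(traj)
        assert profile.values[0] == pytest.approx(0.30, abs=0.01)
        assert profile.values[1] == pytest.approx(np.sqrt(0.03), abs=0.01)

    def test_residue_reduction_means_atom_values(self):
        positions = np.zeros((2, 3))
        system = make_point_charge_system(positions, np.zeros(2))
        # one residue with two atoms, neither named CA
        system.atoms[1].residue_id = system.atoms[0].residue_id
        system._residues = None
        rng = np.random.default_rng(10)
        frames = positions[None] + rng.normal(
            scale=[[0.2], [0.4]], size=(5000, 2, 3)
        ) / np.sqrt(3)
        traj = Trajectory(system, frames)
        atom_profile = rmsf_profile(traj)
        res_profile = rmsf_profile(traj, by_residue=True)
        assert res_profile.values[0] == pytest.approx(atom_profile.values.mean(), rel=1e-10)

    def test_rmsf_difference_sign_convention(self):
        wt = make_fluctuation_trajectory(
            np.zeros((2, 3)), np.full((2, 3), 0.2), n_frames=4000, seed=11
        )
        mut = make_fluctuation_trajectory(
            np.zeros((2, 3)), np.full((2, 3), 0.4), n_frames=4000, seed=12
        )
        diff = rmsf_difference(
            rmsf_profile(wt, by_residue=True), rmsf_profile(mut, by_residue=True)
        )
        # mutant fluctuates more: b - a positive, near sqrt(3)*(0.4-0.2)
        for v in diff.values():
            assert v == pytest.approx(np.sqrt(3) * 0.2, abs=0.05)

    def test_invariance_under_global_rigid_motion(self):
        traj = make_fluctuation_trajectory(
            np.zeros((4, 3)), np.full((4, 3), 0.3), n_frames=2000, seed=13
        )
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        moved = Trajectory(
            traj.topology, rot.apply(traj.frames.reshape(-1, 3)).reshape(traj.frames.shape) + 5.0
        )
        np.testing.assert_allclose(
            rmsf_profile(moved).values, rmsf_profile(traj).values, rtol=1e-10
        )


class TestCrossCorrelation:
    def test_diagonal_is_one(self):
        traj = make_fluctuation_trajectory(
            np.zeros((3, 3)), np.full((3, 3), 0.2), n_frames=100, seed=14
        )
        c = cross_correlation(traj)
        np.testing.assert_allclose(np.diag(c.matrix), 1.0)

    def test_perfectly_correlated_and_anticorrelated(self):
        traj = make_fluctuation_trajectory(
            np.zeros((3, 3)),
            np.full((3, 3), 0.3),
            pair_correlations={(0, 1): 1.0, (0, 2): -1.0, (1, 2): -1.0},
            n_frames=500,
            seed=15,
        )
        c = cross_correlation(traj).matrix
        assert c[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert c[0, 2] == pytest.approx(-1.0, abs=1e-9)

    def test_intermediate_correlation_recovered(self):
        traj = make_fluctuation_trajectory(
            np.zeros((2, 3)),
            np.full((2, 3), 0.3),
            pair_correlations={(0, 1): 0.5},
            n_frames=10_000,
            seed=16,
        )
        c = cross_correlation(traj).matrix
        assert c[0, 1] == pytest.approx(0.50, abs=0.02)

    def test_symmetric_and_psd(self):
        traj = make_fluctuation_trajectory(
            np.zeros((5, 3)),
            np.full((5, 3), 0.25),
            pair_correlations={(0, 1): 0.4, (2, 3): -0.3},
            n_frames=3000,
            seed=17,
        )
        c = cross_correlation(traj).matrix
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.linalg.eigvalsh(c).min() > -1e-8


class TestHbonds:
    @staticmethod
    def dha_trajectory(present_frames, total_frames, angle=180.0, r_da=2.8):
        """Donor at origin, H on x-axis, acceptor placed per frame."""
        positions = np.array([[0.0, 0, 0], [1.0, 0, 0], [r_da, 0, 0]])
        system = make_point_charge_system(positions, np.zeros(3))
        system.atoms[0].name = "N"
        system.atoms[1].name = "H"
        system.atoms[2].name = "O"
        frames = np.tile(positions, (total_frames, 1, 1))
        theta = np.radians(180.0 - angle)
        acceptor_near = np.array(
            [1.0 + (r_da - 1.0) * np.cos(theta), (r_da - 1.0) * np.sin(theta), 0.0]
        )
        for f in range(total_frames):
            frames[f, 2] = acceptor_near if f < present_frames else [20.0, 0, 0]
        return Trajectory(system, frames)

    def test_constructed_40_percent_occupancy(self):
        traj = self.dha_trajectory(present_frames=40, total_frames=100)
        bonds = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2])
        assert len(bonds) == 1
        assert bonds[0].occupancy == pytest.approx(0.40)
        assert filter_hbonds(bonds, 0.30) == bonds
        assert filter_hbonds(bonds, 0.50) == []

    def test_linear_geometry_at_28_is_present(self):
        traj = self.dha_trajectory(present_frames=1, total_frames=1, angle=180.0, r_da=2.8)
        bonds = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2])
        assert bonds[0].occupancy == 1.0

    def test_bent_geometry_rejected_by_angle_cut(self):
        traj = self.dha_trajectory(present_frames=1, total_frames=1, angle=100.0, r_da=2.8)
        bonds = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2], angle_cut=135.0)
        assert bonds[0].occupancy == 0.0

    def test_matches_brute_force_on_random_geometry(self):
        rng = np.random.default_rng(18)
        positions = rng.uniform(-3, 3, size=(4, 3))
        system = make_point_charge_system(positions, np.zeros(4))
        frames = positions[None] + rng.normal(scale=1.0, size=(50, 4, 3))
        traj = Trajectory(system, frames)
        bonds = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2, 3],
                                d_cut=3.0, angle_cut=135.0)
        for bond in bonds:
            count = 0
            for f in range(50):
                d, h, a = frames[f, bond.donor], frames[f, bond.hydrogen], frames[f, bond.acceptor]
                if np.linalg.norm(a - d) > 3.0:
                    continue
                v1, v2 = d - h, a - h
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 135.0:
                    count += 1
            assert bond.occupancy == pytest.approx(count / 50)
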