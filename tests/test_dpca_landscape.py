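"""Dihedral PCA, free-energy surfaces, basins, Kabsch RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conformetry.dpca_landscape import (KB_KJ_PER_MOL_K, FreeEnergySurface,
                                        dpca, fes_histogram, find_basins,
                                        kabsch_rmsd, rmsd_matrix,
                                        sincos_embed)
from conformetry.synthetic_traj import TrajectoryConfig, simulate_trajectory


@pytest.fixture(scope="module")
def two_state_traj():
    cfg = TrajectoryConfig(n_frames=40_000, p_ab=0.005, p_ba=0.010, seed=42)
    return simulate_trajectory(cfg)


class TestEmbed:
    def test_cardinal_angles(self):
        emb = sincos_embed(np.array([[0.0, np.pi / 2]]))
        np.testing.assert_allclose(emb, [[1.0, 0.0, 0.0, 1.0]], atol=1e-12)

    def test_unit_norm_pairs(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-np.pi, np.pi, (100, 7))
        emb = sincos_embed(angles)
        norms = emb[:, 0::2] ** 2 + emb[:, 1::2] ** 2
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


class TestDpca:
    def test_constant_trajectory_zero_variance(self):
        with pytest.warns(UserWarning, match="constant"):
            res = dpca(np.ones((50, 6)))
        assert res.total_variance == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 8)) @ rng.normal(size=(8, 8))
        res = dpca(X)
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance,
                                                      abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(2)
        res = dpca(rng.normal(size=(200, 6)))
        gram = res.components.T @ res.components
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_two_cluster_recovery(self, two_state_traj):
        """PC1 sign separates the two hidden states for >= 99 % of
        frames."""
        res = dpca(sincos_embed(two_state_traj))
        pc1 = res.projections[:, 0]
        truth = two_state_traj.truth_states
        assign = (pc1 > 0).astype(int)
        acc = max(np.mean(assign == truth), np.mean(assign != truth))
        assert acc >= 0.99

    def test_column_permutation_invariance(self, two_state_traj):
        """Relabelling dihedral columns permutes features but leaves the
        spectrum (and PC1 up to sign) unchanged."""
        angles = two_state_traj.angles[:2000]
        rng = np.random.default_rng(3)
        perm = rng.permutation(angles.shape[1])
        r1 = dpca(sincos_embed(angles))
        r2 = dpca(sincos_embed(angles[:, perm]))
        np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-8)
        corr = np.corrcoef(r1.projections[:, 0], r2.projections[:, 0])[0, 1]
        assert abs(corr) > 1.0 - 1e-8


class TestFes:
    def test_single_bin(self):
        proj = np.zeros((100, 2))
        fes = fes_histogram(proj, bins=5)
        assert fes.grid.count() == 1
        assert float(fes.grid.min()) == 0.0

    def test_two_bin_delta_g_closed_form(self):
        """Probabilities 2/3 vs 1/3 at 300 K differ by kB*300*ln2 =
        1.729 kJ/mol."""
        proj = np.array([[0.0, 0.0]] * 200 + [[1.0, 0.0]] * 100)
        fes = fes_histogram(proj, bins=2, temperature_K=300.0)
        vals = np.sort(fes.grid.compressed())
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(KB_KJ_PER_MOL_K * 300.0 * np.log(2.0),
                                        abs=1e-9)

    def test_uniform_occupancy_all_zero(self):
        # one sample per bin of a 2 x 2 grid
        proj = np.array([[0.25, 0.25], [0.25, 0.75], [0.75, 0.25], [0.75, 0.75]])
        fes = fes_histogram(proj, bins=2)
        np.testing.assert_allclose(fes.grid.compressed(), 0.0, atol=1e-12)

    def test_invariant_to_count_rescaling(self, two_state_traj):
        res = dpca(sincos_embed(two_state_traj))
        p = res.projections
        f1 = fes_histogram(p, bins=30)
        f2 = fes_histogram(np.vstack([p, p, p]), bins=30)
        np.testing.assert_allclose(f1.grid.filled(np.nan),
                                   f2.grid.filled(np.nan), atol=1e-9,
                                   equal_nan=True)

    def test_minimum_is_exactly_zero(self, two_state_traj):
        res = dpca(sincos_embed(two_state_traj))
        fes = fes_histogram(res.projections)
        assert float(fes.grid.min()) == 0.0
        assert np.all(fes.grid.compressed() >= 0.0)


class TestBasins:
    def test_single_well(self):
        rng = np.random.default_rng(4)
        proj = rng.normal(size=(20_000, 2))
        fes = fes_histogram(proj, bins=30)
        basins = find_basins(fes)
        assert len(basins.minima) == 1
        assert basins.occupancy_ratio is None
        assert basins.barrier_kj_mol is None

    def test_hand_built_flooding_barrier(self):
        """1-row grid [0, 2, 0.5]: two basins, barrier 2.0 - 0.5 = 1.5
        from the shallower minimum."""
        grid = np.ma.masked_array([[0.0, 2.0, 0.5]], mask=[[False] * 3])
        fes = FreeEnergySurface(grid=grid,
                                bin_edges=(np.arange(2.0), np.arange(4.0)))
        basins = find_basins(fes, min_occupancy=0.0)
        assert len(basins.minima) == 2
        assert basins.barrier_kj_mol == pytest.approx(1.5)
        assert basins.occupancy_ratio >= 1.0

    def test_basin_masses_match_hidden_states(self, two_state_traj):
        """FES basin occupancies reproduce the hidden-state split of the
        same trajectory to within 5 %."""
        res = dpca(sincos_embed(two_state_traj))
        fes = fes_histogram(res.projections)
        basins = find_basins(fes)
        assert len(basins.minima) == 2
        occ_a = np.mean(two_state_traj.truth_states == 0)
        truth_ratio = max(occ_a, 1 - occ_a) / min(occ_a, 1 - occ_a)
        assert basins.occupancy_ratio == pytest.approx(truth_ratio, rel=0.05)

    def test_empty_surface_rejected(self):
        grid = np.ma.masked_array([[0.0]], mask=[[True]])
        fes = FreeEnergySurface(grid=grid,
                                bin_edges=(np.arange(2.0), np.arange(2.0)))
        with pytest.raises(ValueError):
            find_basins(fes)


class TestKabsch:
    def _random_points(self, n=12, seed=0):
        return np.random.default_rng(seed).normal(size=(n, 3))

    def test_identical_sets_zero(self):
        a = self._random_points()
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        a = self._random_points(seed=1)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        b = a @ rot.T + np.array([5.0, -2.0, 7.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = self._random_points(seed=2)
        b = self._random_points(seed=3)
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-9)

    def test_reflection_not_allowed(self):
        """A mirrored chiral set keeps a positive RMSD (proper rotations
        only)."""
        a = self._random_points(seed=4)
        b = a.copy()
        b[:, 0] *= -1.0
        assert kabsch_rmsd(a, b) > 0.1

    def test_displaced_vertex_matches_rotation_grid_oracle(self):
        """Unit triangle vs the same with one vertex moved 0.3: compare
        to exhaustive search over a fine rotation grid."""
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        b = a.copy()
        b[2, 1] += 0.3
        got = kabsch_rmsd(a, b)
        ca, cb = a - a.mean(0), b - b.mean(0)
        best = np.inf
        grid = np.linspace(-0.25, 0.25, 41)   # fine grid around identity
        for ax in grid:
            for ay in grid:
                for az in grid:
                    R = Rotation.from_euler("xyz", [ax, ay, az]).as_matrix()
                    rmsd = np.sqrt(np.mean(np.sum((ca - cb @ R.T) ** 2, axis=1)))
                    best = min(best, rmsd)
        assert got == pytest.approx(best, abs=1e-3)
        assert got <= best + 1e-9

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(self._random_points(5), self._random_points(6))


class TestRmsdMatrix:
    def test_duplicate_frames_all_zero(self):
        a = np.random.default_rng(5).normal(size=(8, 3))
        mat, mx = rmsd_matrix([a, a.copy(), a.copy()])
        np.testing.assert_allclose(mat, 0.0, atol=1e-9)
        assert mx == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_zero_diagonal_and_max(self):
        rng = np.random.default_rng(6)
        frames = [rng.normal(size=(10, 3)) for _ in range(3)]
        mat, mx = rmsd_matrix(frames)
        np.testing.assert_allclose(mat, mat.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(mat), 0.0, atol=1e-12)
        brute = max(kabsch_rmsd(frames[i], frames[j])
                    for i in range(3) for j in range(i + 1, 3))
        assert mx == pytest.approx(brute, abs=1e-12)
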