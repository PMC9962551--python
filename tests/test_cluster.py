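import numpy as np
import pytest

from cyptraj.cluster import (
    RmsdMatrix,
    gromos_cluster,
    kabsch_superpose,
    pairwise_rmsd,
    representative_pose,
)

from conftest import make_trajectory, random_rotation


def quaternion_rmsd(X, Y):
    """Horn's quaternion method: independent oracle for the optimal RMSD."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = len(X)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Xc
    K = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(Xc**2) + np.sum(Yc**2) - 2.0 * lam) / n
    return np.sqrt(max(msd, 0.0))


def daura_reference(values, cutoff):
    """Exhaustive set-based reimplementation of the Daura procedure (oracle)."""
    n = len(values)
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_neighbors = None, None
        for i in sorted(remaining):
            neighbors = {j for j in remaining if values[i][j] <= cutoff}
            if best is None or len(neighbors) > len(best_neighbors):
                best, best_neighbors = i, neighbors
        clusters.append((best, frozenset(best_neighbors)))
        remaining -= best_neighbors
    return clusters


class TestKabsch:
    def test_identity_when_equal(self, rng):
        X = rng.standard_normal((6, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_transform(self, rng):
        X = rng.standard_normal((8, 3))
        R0 = random_rotation(rng)
        Y = (X - 0.3) @ R0.T + 1.7
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        X = rng.standard_normal((10, 3))
        Y = X * np.array([-1.0, 1.0, 1.0])  # mirror image
        R, _, _ = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry(self, rng):
        X, Y = rng.standard_normal((2, 7, 3))
        _, _, ab = kabsch_superpose(X, Y)
        _, _, ba = kabsch_superpose(Y, X)
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_matches_quaternion_oracle_on_random_instances(self, rng):
        for _ in range(100):
            X = rng.standard_normal((5, 3))
            Y = rng.standard_normal((5, 3))
            _, _, rmsd = kabsch_superpose(X, Y)
            assert rmsd == pytest.approx(quaternion_rmsd(X, Y), abs=1e-8)

    def test_point_count_mismatch_and_degenerate(self, rng):
        with pytest.raises(ValueError, match="differ"):
            kabsch_superpose(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, rng.standard_normal((5, 3)))


class TestPairwiseRmsd:
    def test_identical_frames_give_zero_matrix(self, rng):
        frame = rng.standard_normal((5, 3))
        traj = make_trajectory([frame, frame])
        m = pairwise_rmsd(traj, np.arange(5))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-10)

    def test_distinct_poses_have_positive_offdiagonal(self, rng):
        a = rng.standard_normal((5, 3))
        b = a + rng.standard_normal((5, 3))  # different internal geometry
        m = pairwise_rmsd(make_trajectory([a, b]), np.arange(5))
        assert m.values[0, 1] > 0

    def test_matches_elementwise_oracle(self, rng):
        traj = make_trajectory(rng.standard_normal((8, 6, 3)))
        m = pairwise_rmsd(traj, np.arange(6))
        for i in range(8):
            for j in range(8):
                expected = 0.0 if i == j else quaternion_rmsd(traj.coords[i], traj.coords[j])
                assert m.values[i, j] == pytest.approx(expected, abs=1e-8)

    def test_fit_selection_split(self, rng):
        """Fitting on a rigid scaffold, measuring on a moving ligand."""
        scaffold = rng.standard_normal((6, 3))
        lig0 = rng.standard_normal((4, 3)) * 0.2
        shift = np.array([0.5, 0.0, 0.0])
        frames = []
        for lig in (lig0, lig0 + shift):
            R = random_rotation(rng)
            t = rng.uniform(-2, 2, 3)
            frames.append(np.vstack([scaffold, lig]) @ R.T + t)
        traj = make_trajectory(frames)
        m = pairwise_rmsd(traj, np.arange(6, 10), fit_selection=np.arange(6))
        assert m.values[0, 1] == pytest.approx(0.5, abs=1e-8)


class TestGromos:
    def test_all_within_cutoff_single_cluster(self):
        v = np.full((4, 4), 0.1)
        np.fill_diagonal(v, 0.0)
        cs = gromos_cluster(RmsdMatrix(np.arange(4), v), cutoff=0.3)
        assert cs.n_clusters == 1
        assert sorted(cs.clusters[0]) == [0, 1, 2, 3]

    def test_all_beyond_cutoff_all_singletons(self):
        v = np.full((5, 5), 0.9)
        np.fill_diagonal(v, 0.0)
        cs = gromos_cluster(RmsdMatrix(np.arange(5), v), cutoff=0.3)
        assert cs.n_clusters == 5
        assert cs.sizes == [1] * 5

    def test_matches_exhaustive_daura_reference(self, rng):
        for trial in range(40):
            n = int(rng.integers(2, 11))
            d = rng.uniform(0, 1, (n, n))
            v = (d + d.T) / 2
            np.fill_diagonal(v, 0.0)
            cutoff = float(rng.uniform(0.2, 0.8))
            cs = gromos_cluster(RmsdMatrix(np.arange(n), v), cutoff=cutoff)
            ref = daura_reference(v, cutoff)
            assert cs.centers == [c for c, _ in ref]
            assert [frozenset(c) for c in cs.clusters] == [m for _, m in ref]

    def test_partition_covers_all_frames_once(self, rng):
        n = 12
        d = rng.uniform(0, 1, (n, n))
        v = (d + d.T) / 2
        np.fill_diagonal(v, 0.0)
        cs = gromos_cluster(RmsdMatrix(np.arange(n), v), cutoff=0.4)
        flat = sorted(f for c in cs.clusters for f in c)
        assert flat == list(range(n))

    def test_decreasing_cutoff_never_decreases_cluster_count(self, rng):
        n = 10
        d = rng.uniform(0, 1, (n, n))
        v = (d + d.T) / 2
        np.fill_diagonal(v, 0.0)
        m = RmsdMatrix(np.arange(n), v)
        counts = [gromos_cluster(m, cutoff=c).n_clusters for c in (0.8, 0.6, 0.4, 0.2, 0.1)]
        assert counts == sorted(counts)


class TestRepresentativePose:
    def test_center_of_most_populated_cluster(self, rng):
        traj = make_trajectory(rng.standard_normal((10, 4, 3)))
        from cyptraj.cluster import ClusterSet

        cs = ClusterSet(clusters=[[3, 1, 2], [0, 4, 5, 6, 7, 8, 9]], centers=[1, 6], cutoff=0.3)
        pose = representative_pose(traj, cs)
        np.testing.assert_array_equal(pose.coords, traj.coords[6])

    def test_population_tie_takes_first_cluster(self, rng):
        traj = make_trajectory(rng.standard_normal((4, 4, 3)))
        from cyptraj.cluster import ClusterSet

        cs = ClusterSet(clusters=[[0, 1], [2, 3]], centers=[0, 3], cutoff=0.3)
        pose = representative_pose(traj, cs)
        np.testing.assert_array_equal(pose.coords, traj.coords[0])
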