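"""Superposition, RMSD/RMSF, RDF, hydration counting, frame clustering."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from orcakit import synthetic, traj
from orcakit.types import Trajectory

from oracles import quaternion_superpose_rmsd


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_rigid_copy_superposes_exactly(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(12, 3))
        mobile = ref @ random_rotation(rng).T + np.array([3.0, -1.0, 7.0])
        _, _, rmsd = traj.kabsch_superpose(mobile, ref)
        assert rmsd <= 1e-8

    def test_reflected_square_needs_proper_rotation(self):
        # a planar square and its mirror image: a reflection would fit with
        # zero residual, a proper rotation cannot
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, 1.0]])
        mobile = ref * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = traj.kabsch_superpose(mobile, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        # brute-force minimum over a dense SO(3) grid
        rng = np.random.default_rng(1)
        best = min(
            np.sqrt(np.mean(np.sum((
                (mobile - mobile.mean(0)) @ random_rotation(rng).T
                - (ref - ref.mean(0))) ** 2, axis=1)))
            for _ in range(200_000)
        )
        assert rmsd <= best + 1e-3

    def test_matches_quaternion_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = rng.normal(size=(10, 3)) * 5
            b = rng.normal(size=(10, 3)) * 5
            _, _, rmsd = traj.kabsch_superpose(a, b)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-9)

    def test_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        r1 = traj.kabsch_superpose(a, b)[2]
        r2 = traj.kabsch_superpose(b, a)[2]
        moved = a @ random_rotation(rng).T + 11.0
        r3 = traj.kabsch_superpose(moved, b)[2]
        assert r1 == pytest.approx(r2, abs=1e-8)
        assert r1 == pytest.approx(r3, abs=1e-8)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            traj.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            traj.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSDSeries:
    def test_static_trajectory_all_zero(self):
        t = synthetic.simulate_trajectory(5, n_ca=6, n_waters=0, fluct_sigma=0.0,
                                          rigid_motion=False, seed=0)
        assert np.allclose(traj.rmsd_series(t), 0.0)

    def test_rigid_motion_only_removed_by_fitting(self):
        t = synthetic.simulate_trajectory(10, n_ca=8, n_waters=0, fluct_sigma=0.0,
                                          rigid_motion=True, seed=1)
        assert np.all(traj.rmsd_series(t) <= 1e-8)

    def test_fluctuating_trajectory_matches_per_frame_oracle(self):
        t = synthetic.simulate_trajectory(50, n_ca=20, n_waters=0, fluct_sigma=0.3,
                                          seed=2)
        series = traj.rmsd_series(t, ref_frame=0)
        x = t.select("ca")
        oracle = [quaternion_superpose_rmsd(x[f], x[0]) for f in range(50)]
        assert np.allclose(series, oracle, atol=1e-9)
        assert series[0] <= 1e-12


class TestRMSF:
    def test_static_atoms_zero(self):
        t = synthetic.simulate_trajectory(5, n_ca=6, n_waters=0, fluct_sigma=0.0,
                                          rigid_motion=True, seed=3)
        assert np.allclose(traj.rmsf(t), 0.0, atol=1e-8)

    def test_isotropic_gaussian_closed_form(self):
        # sigma*sqrt(3) per atom; 60 atoms so the 6 rigid-body DOF absorbed by
        # superposition shrink RMSF by only sqrt(1 - 6/180) ~ 1.7%
        t = synthetic.simulate_trajectory(2000, n_ca=60, n_waters=0,
                                          fluct_sigma=0.5, seed=4)
        r = traj.rmsf(t)
        assert np.mean(r) == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_rigid_subgroup_below_noisy_subgroup(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(-5, 5, size=(10, 3))
        frames = []
        for _ in range(200):
            noisy = base.copy()
            noisy[5:] += rng.normal(0, 0.8, size=(5, 3))
            noisy[:5] += rng.normal(0, 0.05, size=(5, 3))
            frames.append(noisy)
        t = Trajectory(coords=np.array(frames), roles=np.array(["ca"] * 10))
        r = traj.rmsf(t)
        assert r[:5].max() < r[5:].min()

    def test_invariant_under_global_rigid_motion(self):
        t = synthetic.simulate_trajectory(100, n_ca=10, n_waters=0, fluct_sigma=0.4,
                                          rigid_motion=False, seed=6)
        rng = np.random.default_rng(7)
        rot = random_rotation(rng)
        moved = Trajectory(coords=t.coords @ rot.T + 5.0, roles=t.roles)
        assert np.allclose(traj.rmsf(t), traj.rmsf(moved), atol=1e-8)


VOL = 4.0 / 3.0 * np.pi * 10.0**3


class TestRDF:
    def test_uniform_sphere_is_ideal_gas(self):
        t = synthetic.simulate_trajectory(300, n_ca=3, n_waters=1000,
                                          fluct_sigma=0.0, n_ligand=1,
                                          water_density_profile="uniform",
                                          box_radius=10.0, seed=8)
        prof = traj.rdf(t, r_max=9.0, dr=0.2, volume=VOL)
        mask = prof.n_pairs >= 500
        assert mask.sum() > 10
        assert np.max(np.abs(prof.g[mask] - 1.0)) <= 0.05

    def test_single_fixed_distance_lands_in_one_bin(self):
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 3.05
        t = Trajectory(coords=coords, roles=np.array(["ligand", "water_o"]))
        prof = traj.rdf(t, r_max=5.0, dr=0.1, volume=VOL)
        assert prof.n_pairs[np.digitize(3.05, np.arange(0, 5.05, 0.1)) - 1] == 2
        assert prof.n_pairs.sum() == 2

    def test_gaussian_shell_peak_recovered_within_bin(self):
        t = synthetic.simulate_trajectory(
            200, n_ca=3, n_waters=400, fluct_sigma=0.0, n_ligand=1,
            water_density_profile=("gaussian_shell", 2.8, 0.3),
            box_radius=10.0, seed=9)
        prof = traj.rdf(t, r_max=6.0, dr=0.1, volume=VOL)
        peak = prof.r_centers[np.argmax(prof.g)]
        assert abs(peak - 2.8) <= 0.1

    def test_cumulative_count_integrates_density(self):
        t = synthetic.simulate_trajectory(200, n_ca=3, n_waters=500,
                                          fluct_sigma=0.0, n_ligand=1,
                                          water_density_profile="uniform",
                                          box_radius=10.0, seed=10)
        prof = traj.rdf(t, r_max=9.0, dr=0.1, volume=VOL)
        rho = 500 / VOL
        expected = rho * 4.0 / 3.0 * np.pi * 9.0**3
        n = prof.cumulative_count[-1]
        se = np.sqrt(expected / 200)  # Poisson counting over frames
        assert abs(n - expected) <= 3 * se

    def test_missing_volume_rejected(self):
        t = synthetic.simulate_trajectory(3, seed=0)
        with pytest.raises(ValueError):
            traj.rdf(t, volume=None)


class TestWatersWithin:
    def test_no_waters_zero(self):
        t = synthetic.simulate_trajectory(3, n_ca=4, n_waters=0, seed=0)
        mean, sd, counts = traj.waters_within(t)
        assert mean == 0.0 and np.all(counts == 0)

    def test_exact_count_at_fixed_radii(self):
        lig = np.zeros((1, 3))
        near = np.array([[4.0, 0, 0]]).repeat(10, axis=0) \
            * np.linspace(0.5, 1.0, 10)[:, None]
        far = np.array([[6.0, 0, 0]]).repeat(5, axis=0) \
            + np.arange(5)[:, None] * [0.1, 0, 0]
        frame = np.vstack([lig, near, far])
        coords = np.stack([frame, frame])
        roles = np.array(["ligand"] + ["water_o"] * 15)
        mean, sd, _ = traj.waters_within(Trajectory(coords=coords, roles=roles),
                                         cutoff=5.0)
        assert mean == 10.0 and sd == 0.0

    def test_poisson_density_expectation(self):
        t = synthetic.simulate_trajectory(400, n_ca=3, n_waters=600,
                                          fluct_sigma=0.0, n_ligand=1,
                                          water_density_profile="uniform",
                                          box_radius=10.0, seed=11)
        mean, sd, counts = traj.waters_within(t, cutoff=5.0)
        # ligand cluster has finite extent; bound expectation by spheres
        # around the ligand's atoms -- here a single-atom approximation
        lig = t.select("ligand")
        rho = 600 / VOL
        expected = rho * 4.0 / 3.0 * np.pi * 5.0**3
        se = sd / np.sqrt(400)
        assert abs(mean - expected) <= max(3 * se, 0.05 * expected)


class TestClusterFrames:
    @staticmethod
    def scipy_merge_sets(dist):
        z = linkage(squareform(dist, checks=False), method="average")
        n = dist.shape[0]
        clusters = {i: frozenset([i]) for i in range(n)}
        merges = []
        for k, row in enumerate(z):
            a, b = clusters[int(row[0])], clusters[int(row[1])]
            merges.append(frozenset({a, b}))
            clusters[n + k] = a | b
        return merges

    def test_merge_sequence_matches_scipy_oracle_on_small_random_cases(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, 3))
            dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            ours = [frozenset({a, b})
                    for a, b in traj.average_linkage_merges(dist)]
            assert ours == self.scipy_merge_sets(dist)

    def test_two_conformer_trajectory_partitioned_exactly(self):
        rng = np.random.default_rng(13)
        conf_a = rng.uniform(-5, 5, size=(10, 3))
        conf_b = conf_a + np.array([8.0, 0, 0]) * rng.normal(1, 0.1, size=(10, 1))
        frames, labels = [], []
        for i in range(20):
            base = conf_a if i % 2 == 0 else conf_b
            frames.append(base + rng.normal(0, 0.1, size=(10, 3)))
            labels.append(i % 2)
        t = Trajectory(coords=np.array(frames), roles=np.array(["ca"] * 10))
        res = traj.cluster_frames(t, k=2)
        got = res.labels
        expected = np.array(labels)
        same = np.array_equal(got, expected) or np.array_equal(got, 1 - expected)
        assert same

    def test_identical_frames_single_cluster_rep_zero(self):
        coords = np.repeat(np.random.default_rng(14).normal(size=(1, 6, 3)), 5, axis=0)
        t = Trajectory(coords=coords, roles=np.array(["ca"] * 6))
        res = traj.cluster_frames(t, k=1)
        assert np.all(res.labels == 0)
        assert res.representatives.tolist() == [0]

    def test_permutation_equivariance(self):
        t = synthetic.simulate_trajectory(12, n_ca=8, n_waters=0, fluct_sigma=1.0,
                                          seed=15)
        res = traj.cluster_frames(t, k=3)
        perm = np.random.default_rng(16).permutation(12)
        t2 = Trajectory(coords=t.coords[perm], roles=t.roles)
        res2 = traj.cluster_frames(t2, k=3)
        # canonical relabeling: compare the induced partitions of frame ids
        def partition(labels, order):
            groups = {}
            for pos, lab in enumerate(labels):
                groups.setdefault(lab, set()).add(order[pos])
            return {frozenset(v) for v in groups.values()}
        assert partition(res.labels, np.arange(12)) == partition(res2.labels, perm)

    def test_k_bounds_enforced(self):
        t = synthetic.simulate_trajectory(4, n_ca=5, n_waters=0, seed=17)
        with pytest.raises(ValueError):
            traj.cluster_frames(t, k=5)

    def test_representative_minimizes_mean_rmsd(self):
        t = synthetic.simulate_trajectory(15, n_ca=6, n_waters=0, fluct_sigma=0.5,
                                          seed=18)
        res = traj.cluster_frames(t, k=2)
        for lab in (0, 1):
            members = np.nonzero(res.labels == lab)[0]
            if len(members) < 2:
                continue
            sub = res.rmsd_matrix[np.ix_(members, members)]
            means = sub.sum(axis=1) / (len(members) - 1)
            assert res.representatives[lab] == members[np.argmin(means)]
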