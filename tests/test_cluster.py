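import math

import numpy as np
import pytest

from mirloc import (
    ClusterParams,
    Rect,
    cell_summary,
    cluster_metrics,
    collapse_repeated_localizations,
    critical_density,
    csr_test,
    density_cluster,
    mutual_nearest_pair_distances,
    sample_csr,
    sample_thomas,
)


def brute_force_dbscan(points, radius, k):
    """O(n^2) reference clustering with the same semantics: core points have
    >= k neighbours within radius (self excluded), clusters are connected
    components of cores, border points join their nearest core."""
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.hypot(points[:, None, 0] - points[None, :, 0],
                 points[:, None, 1] - points[None, :, 1])
    neigh = (d <= radius)
    core = neigh.sum(axis=1) - 1 >= k
    labels = np.full(n, -1)
    comp = np.full(n, -1)
    cid = 0
    for i in range(n):
        if core[i] and comp[i] < 0:
            stack = [i]
            comp[i] = cid
            while stack:
                u = stack.pop()
                for v in np.nonzero(neigh[u] & core)[0]:
                    if comp[v] < 0:
                        comp[v] = cid
                        stack.append(v)
            cid += 1
    labels[core] = comp[core]
    for i in np.nonzero(~core)[0]:
        cores_in_range = np.nonzero(neigh[i] & core)[0]
        if len(cores_in_range):
            labels[i] = comp[cores_in_range[np.argmin(d[i, cores_in_range])]]
    return labels


def labels_equivalent(a, b):
    """True when two labelings agree up to renaming of cluster ids."""
    if len(a) != len(b):
        return False
    if ((a < 0) != (b < 0)).any():
        return False
    fwd, bwd = {}, {}
    for x, y in zip(a[a >= 0], b[a >= 0]):
        if fwd.setdefault(x, y) != y or bwd.setdefault(y, x) != x:
            return False
    return True


class TestCriticalDensity:
    def test_results_preset(self):
        # 5 neighbours within 120 nm <-> 132 molecules per um^2
        rho = critical_density(5, 120.0)
        assert rho == pytest.approx(132.63, abs=0.01)
        assert math.floor(rho) == 132

    def test_methods_preset(self):
        # 5 neighbours within 60 nm <-> 530 points per um^2
        rho = critical_density(5, 60.0)
        assert rho == pytest.approx(530.52, abs=0.01)
        assert math.floor(rho) == 530

    def test_forced_by_formula(self):
        assert critical_density(0, 100.0) == pytest.approx(1 / (math.pi * 0.01),
                                                           rel=1e-12)
        assert math.floor(critical_density(0, 100.0)) == 31

    def test_invalid(self):
        with pytest.raises(ValueError):
            critical_density(5, 0.0)

    def test_presets_reproduce_printed_densities(self):
        # the shipped presets tie the neighbour criterion to the density form
        for name, printed in (("results", 132), ("methods", 530)):
            p = ClusterParams.from_preset(name)
            assert math.floor(critical_density(p.min_neighbors,
                                               p.radius_nm)) == printed


class TestDensityCluster:
    def test_pentagon_plus_center(self):
        ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        pts = np.vstack([50.0 * np.column_stack([np.cos(ang), np.sin(ang)]),
                         [[0.0, 0.0]]])
        res = density_cluster(pts, ClusterParams(radius_nm=120.0,
                                                 min_neighbors=5))
        assert res.n_clusters == 1
        assert (res.labels == 0).all()

    def test_isolated_points_noise(self):
        pts = np.array([[0, 0], [500, 0], [0, 500], [900, 900], [1500, 200]],
                       dtype=float)
        res = density_cluster(pts, ClusterParams.from_preset("results"))
        assert (res.labels == -1).all()
        assert res.n_clusters == 0

    def test_empty(self):
        res = density_cluster(np.empty((0, 2)), ClusterParams())
        assert res.n_clusters == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        region = Rect(0, 0, 3000, 3000)
        sc = sample_thomas(6, 15.0, 40.0, 150, region, seed=seed)
        params = ClusterParams.from_preset("results")
        res = density_cluster(sc.positions, params)
        oracle = brute_force_dbscan(sc.positions, params.radius_nm,
                                    params.min_neighbors)
        assert labels_equivalent(res.labels, oracle)

    def test_permutation_invariance(self):
        region = Rect(0, 0, 3000, 3000)
        sc = sample_thomas(5, 20.0, 40.0, 100, region, seed=11)
        params = ClusterParams.from_preset("results")
        a = density_cluster(sc.positions, params).labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(a))
        b = density_cluster(sc.positions[perm], params).labels
        assert labels_equivalent(a[perm], b)

    def test_rigid_motion_invariance(self):
        region = Rect(0, 0, 3000, 3000)
        sc = sample_thomas(5, 20.0, 40.0, 100, region, seed=12)
        params = ClusterParams.from_preset("results")
        a = density_cluster(sc.positions, params).labels
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = sc.positions @ rot.T + [12345.0, -9876.0]
        b = density_cluster(moved, params).labels
        assert labels_equivalent(a, b)


class TestClusterMetrics:
    def square_result(self):
        pts = np.array([[0, 0], [100, 0], [0, 100], [100, 100]], dtype=float)
        res = density_cluster(pts, ClusterParams(radius_nm=150.0,
                                                 min_neighbors=2))
        assert res.n_clusters == 1
        return res, pts

    def test_square_diameter(self):
        res, pts = self.square_result()
        m = cluster_metrics(res, pts)
        assert m.loc[0, "diameter_nm"] == pytest.approx(100 * np.sqrt(2),
                                                        abs=1e-9)

    def test_square_internal_density(self):
        res, pts = self.square_result()
        m = cluster_metrics(res, pts)
        r_um = 100 * np.sqrt(2) / 2 / 1000
        assert m.loc[0, "internal_density_per_um2"] == pytest.approx(
            4 / (math.pi * r_um ** 2), rel=1e-9)
        assert m.loc[0, "internal_density_per_um2"] == pytest.approx(254.6,
                                                                     abs=0.1)

    def test_rotation_invariant_diameter(self):
        region = Rect(0, 0, 2000, 2000)
        sc = sample_thomas(3, 20.0, 30.0, 0, region, seed=4)
        params = ClusterParams.from_preset("results")
        res = density_cluster(sc.positions, params)
        m1 = cluster_metrics(res, sc.positions)
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = sc.positions @ rot.T
        res2 = density_cluster(moved, params)
        m2 = cluster_metrics(res2, moved)
        np.testing.assert_allclose(np.sort(m1["diameter_nm"]),
                                   np.sort(m2["diameter_nm"]), rtol=1e-9)

    def test_gyration_mode_smaller(self):
        res, pts = self.square_result()
        g = cluster_metrics(res, pts, diameter_mode="gyration")
        assert g.loc[0, "diameter_nm"] == pytest.approx(2 * np.sqrt(100 ** 2 / 2),
                                                        rel=1e-9)


class TestCellSummary:
    def test_printed_arithmetic(self):
        class R:
            n_clusters = 40

        s = cell_summary(R(), 19.68)
        assert s["cluster_density_per_um2"] == pytest.approx(40 / 19.68,
                                                             abs=1e-6)

    def test_zero_clusters(self):
        class R:
            n_clusters = 0

        assert cell_summary(R(), 10.0)["cluster_density_per_um2"] == 0.0

    def test_inverse_area_scaling(self):
        class R:
            n_clusters = 8

        assert cell_summary(R(), 4.0)["cluster_density_per_um2"] == \
            2 * cell_summary(R(), 8.0)["cluster_density_per_um2"]

    def test_nonpositive_area(self):
        class R:
            n_clusters = 1

        with pytest.raises(ValueError):
            cell_summary(R(), 0.0)


class TestCSRTest:
    def test_clustered_scene_minimal_p(self):
        region = Rect(0, 0, 5000, 5000)
        sc = sample_thomas(10, 30.0, 20.0, 0, region, seed=3)
        r = csr_test(sc.positions, region, ClusterParams.from_preset("results"),
                     n_sim=99, seed=7)
        assert r.p_value == pytest.approx(1 / 100)
        assert r.statistic == 1.0

    def test_too_few_points(self):
        region = Rect(0, 0, 1000, 1000)
        with pytest.warns(UserWarning):
            r = csr_test(np.array([[1.0, 1.0]]), region, ClusterParams(),
                         n_sim=19, seed=1)
        assert r.p_value == 1.0

    def test_p_value_upper_bound(self):
        # a pattern no more clustered than CSR: every simulation ties or
        # beats it, p = 1
        region = Rect(0, 0, 10_000, 10_000)
        pts = sample_csr(10, region, seed=5).positions  # too sparse to cluster
        r = csr_test(pts, region, ClusterParams.from_preset("results"),
                     n_sim=19, seed=2)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_nsim_floor(self):
        with pytest.raises(ValueError):
            csr_test(np.zeros((10, 2)), Rect(0, 0, 1, 1), ClusterParams(),
                     n_sim=5, seed=1)


class TestPairingHelpers:
    def test_collapse_merges_repeats(self):
        rng = np.random.default_rng(0)
        truth = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        reps = np.concatenate([t + rng.normal(0, 3, size=(5, 2))
                               for t in truth])
        merged = collapse_repeated_localizations(reps, radius_nm=15.0)
        assert len(merged) == 3
        d = np.sort([np.hypot(*(m - t)).min() for m in merged
                     for t in truth if np.hypot(*(m - t)) < 50])
        assert (np.asarray(d) < 10).all()

    def test_mutual_nn_pairs(self):
        pts = np.array([[0, 0], [35, 0], [1000, 1000], [1000, 1035]],
                       dtype=float)
        d = mutual_nearest_pair_distances(pts)
        np.testing.assert_allclose(np.sort(d), [35.0, 35.0])
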