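"""k-medoids clustering: dissimilarity construction, PAM vs exhaustive
search, CLARA behavior, and weekly surface partitioning."""

import itertools

import numpy as np
import pytest

import fullcycle.abundance_clustering as ac
import fullcycle.synthetic_landscape as sl
from fullcycle.workflows import blob_clustering_check


def _points(lat, lon, abundance):
    lat = np.asarray(lat, dtype=float)
    return ac.ClusterPoints(
        cell_id=np.arange(len(lat)), lat=lat, lon=np.asarray(lon, dtype=float), abundance=np.asarray(abundance, dtype=float)
    )


def brute_force_kmedoids(D, k):
    """Exhaustive search over all medoid sets; the independent oracle."""
    n = D.shape[0]
    best = None
    for medoids in itertools.combinations(range(n), k):
        total = D[:, medoids].min(axis=1).sum()
        if best is None or total < best[1] - 1e-12:
            best = (medoids, total)
    return best


class TestDissimilarity:
    def test_identical_points_have_zero_dissimilarity(self):
        p = _points([1, 1], [2, 2], [3, 3])
        D = ac.build_dissimilarity(p)
        assert D[0, 1] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        p = _points(rng.uniform(0, 10, 8), rng.uniform(0, 10, 8), rng.uniform(1, 5, 8))
        D = ac.build_dissimilarity(p)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_abundance_only_difference_scaled_by_weight(self):
        # two points at the same location differing by the full abundance
        # range: scaled distance is exactly the abundance weight
        p = _points([5, 5], [5, 5], [1.0, 10.0])
        D = ac.build_dissimilarity(p, abundance_weight=1.0 / 3.0)
        assert D[0, 1] == pytest.approx(1.0 / 3.0)

    def test_degenerate_axis_contributes_zero(self):
        p = _points([1, 2], [7, 7], [4, 4])  # lon and abundance constant
        D = ac.build_dissimilarity(p)
        assert D[0, 1] == pytest.approx(1.0)  # only the lat axis spans [0,1]


class TestPam:
    def test_k_equals_n_gives_zero_objective(self):
        rng = np.random.default_rng(1)
        p = _points(rng.uniform(0, 10, 6), rng.uniform(0, 10, 6), rng.uniform(1, 5, 6))
        D = ac.build_dissimilarity(p)
        medoids, labels, total = ac.pam(D, 6)
        assert total == 0.0
        assert np.array_equal(np.sort(medoids), np.arange(6))

    def test_separated_triplets_recovered(self):
        lat = [0, 0.1, -0.1, 50, 50.1, 49.9, -50, -50.1, -49.9]
        lon = [0, 0.1, -0.1, 50, 50.1, 49.9, -50, -50.1, -49.9]
        p = _points(lat, lon, np.ones(9))
        D = ac.build_dissimilarity(p)
        medoids, labels, total = ac.pam(D, 3)
        groups = [frozenset(np.nonzero(labels == labels[i])[0]) for i in (0, 3, 6)]
        assert set(groups) == {frozenset({0, 1, 2}), frozenset({3, 4, 5}), frozenset({6, 7, 8})}
        oracle_medoids, oracle_total = brute_force_kmedoids(D, 3)
        assert total == pytest.approx(oracle_total)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_search_on_small_instances(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 13))
        p = _points(rng.uniform(0, 10, n), rng.uniform(0, 10, n), rng.uniform(1, 20, n))
        D = ac.build_dissimilarity(p)
        _, _, total = ac.pam(D, k)
        _, oracle_total = brute_force_kmedoids(D, k)
        assert total == pytest.approx(oracle_total)

    @pytest.mark.parametrize("trial", range(20))
    def test_no_worse_than_random_medoids(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, k = 25, 4
        p = _points(rng.uniform(0, 10, n), rng.uniform(0, 10, n), rng.uniform(1, 20, n))
        D = ac.build_dissimilarity(p)
        _, _, total = ac.pam(D, k)
        random_medoids = rng.choice(n, k, replace=False)
        random_total = D[:, random_medoids].min(axis=1).sum()
        assert total <= random_total + 1e-12

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ac.pam(np.zeros((3, 3)), 4)


class TestClara:
    def test_equals_pam_when_subsample_is_full_set(self):
        rng = np.random.default_rng(2)
        n = 30  # below the default sample size 40 + 2k
        p = _points(rng.uniform(0, 10, n), rng.uniform(0, 10, n), rng.uniform(1, 5, n))
        cfg = ac.ClusteringConfig(k=4, seed=9)
        result = ac.clara(p, cfg)
        D = ac.build_dissimilarity(p, cfg.abundance_weight)
        _, _, pam_total = ac.pam(D, 4)
        assert result.total_dissimilarity == pytest.approx(pam_total)

    def test_produces_k_nonempty_clusters(self):
        rng = np.random.default_rng(3)
        n = 200
        p = _points(rng.uniform(0, 10, n), rng.uniform(0, 10, n), rng.uniform(1, 5, n))
        result = ac.clara(p, ac.ClusteringConfig(k=5, seed=4))
        assert set(result.labels) == {1, 2, 3, 4, 5}
        assert result.abundance_share.sum() == pytest.approx(1.0)
        assert len(result.medoid_cell_ids) == 5

    def test_medoids_belong_to_their_clusters(self):
        rng = np.random.default_rng(5)
        p = _points(rng.uniform(0, 10, 80), rng.uniform(0, 10, 80), rng.uniform(1, 5, 80))
        result = ac.clara(p, ac.ClusteringConfig(k=3, seed=6))
        for j, mid in enumerate(result.medoid_cell_ids, start=1):
            assert result.labels[np.nonzero(result.cell_id == mid)[0][0]] == j

    def test_equal_blobs_have_equal_abundance_shares(self):
        out = blob_clustering_check(seed=3)
        assert out["max_share_deviation"] <= 0.02

    def test_point_order_invariance(self):
        rng = np.random.default_rng(7)
        n = 60
        lat, lon, ab = rng.uniform(0, 10, n), rng.uniform(0, 10, n), rng.uniform(1, 5, n)
        p = _points(lat, lon, ab)
        perm = rng.permutation(n)
        p2 = ac.ClusterPoints(cell_id=np.arange(n)[perm], lat=lat[perm], lon=lon[perm], abundance=ab[perm])
        r1 = ac.clara(p, ac.ClusteringConfig(k=3, seed=8, sample_size=n))
        r2 = ac.clara(p2, ac.ClusteringConfig(k=3, seed=8, sample_size=n))
        # compare partitions as sets of cell-id sets
        part1 = {frozenset(r1.cell_id[r1.labels == j]) for j in (1, 2, 3)}
        part2 = {frozenset(r2.cell_id[r2.labels == j]) for j in (1, 2, 3)}
        assert part1 == part2

    def test_abundance_weight_shifts_partition_axis(self):
        # 8 points on a line, abundance alternating low/high: zero weight
        # splits by geography, large weight splits by abundance level
        lat = np.zeros(8)
        lon = np.arange(8.0)
        ab = np.where(np.arange(8) % 2 == 0, 1.0, 100.0)
        geo = ac.clara(_points(lat, lon, ab), ac.ClusteringConfig(k=2, abundance_weight=0.0, seed=1))
        strat = ac.clara(_points(lat, lon, ab), ac.ClusteringConfig(k=2, abundance_weight=50.0, seed=1))
        geo_part = {frozenset(np.nonzero(geo.labels == j)[0]) for j in (1, 2)}
        strat_part = {frozenset(np.nonzero(strat.labels == j)[0]) for j in (1, 2)}
        assert geo_part == {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}
        assert strat_part == {frozenset({0, 2, 4, 6}), frozenset({1, 3, 5, 7})}

    def test_sample_size_below_k_rejected(self):
        p = _points([0, 1, 2], [0, 1, 2], [1, 1, 1])
        with pytest.raises(ValueError):
            ac.clara(p, ac.ClusteringConfig(k=3, sample_size=2))


class TestClusterWeekly:
    def test_labels_partition_occupied_cells(self, grid10, small_cube):
        out = ac.cluster_weekly(small_cube, grid10, ac.ClusteringConfig(k=3, seed=1))
        sp = small_cube.species[0]
        asg = out[(sp, 1)]
        occupied = np.nonzero(small_cube.values[0, 0] > 0)[0]
        assert np.array_equal(np.sort(asg.cell_id), occupied)
        assert set(asg.labels) <= {1, 2, 3}
        assert asg.abundance_share.sum() == pytest.approx(1.0)

    def test_identical_weeks_get_identical_assignments(self, grid10):
        route = np.tile([30.3, -99.6], (52, 1))
        cube = sl.build_cube([sl.SpeciesParams("s", 500.0, route, spread_km=20.0)], grid10)
        out = ac.cluster_weekly(cube, grid10, ac.ClusteringConfig(k=3, seed=2))
        a, b = out[("s", 5)], out[("s", 40)]
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoid_cell_ids, b.medoid_cell_ids)

    def test_fewer_occupied_cells_than_k_falls_back_to_one_cluster(self, grid10):
        vals = np.zeros((1, 1, grid10.n_cells))
        vals[0, 0, [3, 17]] = [5.0, 7.0]
        cube = sl.AbundanceCube(values=vals, species=["s"], weeks=np.array([1]))
        out = ac.cluster_weekly(cube, grid10, ac.ClusteringConfig(k=5, seed=3))
        asg = out[("s", 1)]
        assert asg.k == 1
        assert np.array_equal(asg.labels, [1, 1])
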