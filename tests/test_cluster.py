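import numpy as np
import pytest
from scipy import stats

from helpers import flood_fill_components
from seqrecog.cluster import (
    find_clusters,
    nearest_rank_percentile,
    run_mcs,
    significant_clusters,
    spatial_shuffle_null,
    threshold_map,
)
from seqrecog.errors import InvalidInputError
from seqrecog.grid import make_grid
from seqrecog.window_stats import StatMap


def _tmap(values, df=69, window=3):
    return StatMap(values=np.asarray(values, float), kind="t_contrast",
                   df=df, window_index=window, n=df + 1)


class TestThreshold:
    def test_zero_map_gives_empty_masks(self):
        pos, neg = threshold_map(_tmap(np.zeros(100)), 0.001)
        assert pos.count == 0 and neg.count == 0

    def test_single_extreme_voxel_selected(self):
        v = np.zeros(50)
        v[17] = 10.0
        pos, neg = threshold_map(_tmap(v), 0.001)
        assert np.flatnonzero(pos.values).tolist() == [17]
        assert neg.count == 0

    def test_critical_value_boundary_at_alpha_05_df_69(self):
        # t_crit(.975, 69) = 1.9949: |t| = 2.00 is significant, 1.90 is not
        assert stats.t.ppf(0.975, 69) == pytest.approx(1.995, abs=0.001)
        pos, _ = threshold_map(_tmap([2.00, 1.90]), 0.05)
        assert pos.values.tolist() == [True, False]

    def test_negative_voxels_split_by_sign(self):
        pos, neg = threshold_map(_tmap([8.0, -8.0, 0.0]), 0.001)
        assert pos.values.tolist() == [True, False, False]
        assert neg.values.tolist() == [False, True, False]

    def test_bad_alpha_rejected(self):
        with pytest.raises(InvalidInputError):
            threshold_map(_tmap(np.zeros(3)), 1.5)


class TestFindClusters:
    def test_two_isolated_voxels_two_singletons(self):
        g = make_grid((5, 5, 5))
        mask = np.zeros(g.n_sources, bool)
        mask[[0, 124]] = True  # opposite corners
        cl = find_clusters(mask, g)
        assert sorted(c.size for c in cl) == [1, 1]

    def test_l_shaped_run_is_one_cluster(self):
        g = make_grid((5, 5, 5), connectivity=6)
        vol = np.zeros(g.dims, bool)
        for ijk in [(1, 1, 1), (2, 1, 1), (3, 1, 1), (3, 2, 1), (3, 3, 1)]:
            vol[ijk] = True
        cl = find_clusters(g.extract(vol), g)
        assert len(cl) == 1 and cl[0].size == 5

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity, rng):
        g = make_grid((10, 10, 10), connectivity=connectivity)
        for _ in range(20):
            mask = rng.random(g.n_sources) < 0.2
            got = {
                frozenset(map(tuple, g.source_ijk[c.voxel_ids]))
                for c in find_clusters(mask, g)
            }
            want = {
                frozenset(comp)
                for comp in flood_fill_components(g.embed(mask), connectivity)
            }
            assert got == want

    def test_peak_statistic_recorded(self):
        g = make_grid((3, 3, 3))
        v = np.zeros(27)
        v[[4, 5]] = [6.0, 9.0]
        sm = _tmap(v)
        pos, _ = threshold_map(sm, 0.001)
        cl = find_clusters(pos, g)
        assert cl[0].peak_stat == 9.0 and cl[0].peak_voxel == 5


class TestShuffleNull:
    def test_empty_mask_all_zero_maxima(self, small_grid):
        null = spatial_shuffle_null(0, small_grid, 100, seed=0)
        assert np.array_equal(null, np.zeros(100, int))

    def test_full_mask_maxima_equal_grid_size(self, small_grid):
        null = spatial_shuffle_null(small_grid.n_sources, small_grid, 50, seed=0)
        assert np.array_equal(null, np.full(50, small_grid.n_sources))

    def test_count_above_grid_size_rejected(self, small_grid):
        with pytest.raises(InvalidInputError):
            spatial_shuffle_null(small_grid.n_sources + 1, small_grid, 10, seed=0)

    def test_matches_independent_monte_carlo_oracle(self):
        """P(max cluster >= 2) for m = 5 on 10^3 at 26-connectivity: compare
        the permutation stream with an independently seeded brute-force
        (BFS) Monte-Carlo run."""
        g = make_grid((10, 10, 10))
        null = spatial_shuffle_null(5, g, 1000, seed=42)
        p_impl = np.mean(null >= 2)
        rng = np.random.default_rng(20_000_000)
        hits = 0
        n_oracle = 1000
        for _ in range(n_oracle):
            vox = rng.choice(g.n_sources, 5, replace=False)
            vol = np.zeros(g.dims, bool)
            vol[tuple(g.source_ijk[vox].T)] = True
            hits += max(len(c) for c in flood_fill_components(vol, 26)) >= 2
        assert p_impl == pytest.approx(hits / n_oracle, abs=0.04)

    @pytest.mark.parametrize("m", [2, 3])
    def test_small_mask_closed_form_matches_bfs_statistics(self, m):
        """The m <= 3 analytic path agrees with brute-force labelling of
        independently placed masks (distribution check)."""
        g = make_grid((8, 8, 8), connectivity=18)
        null = spatial_shuffle_null(m, g, 2000, seed=7)
        rng = np.random.default_rng(123)
        brute = []
        for _ in range(2000):
            vox = rng.choice(g.n_sources, m, replace=False)
            vol = np.zeros(g.dims, bool)
            vol[tuple(g.source_ijk[vox].T)] = True
            brute.append(max(len(c) for c in flood_fill_components(vol, 18)))
        for k in range(1, m + 1):
            assert np.mean(null >= k) == pytest.approx(
                np.mean(np.array(brute) >= k), abs=0.04
            )

    def test_null_median_monotone_in_mask_count(self, rng):
        g = make_grid((10, 10, 10))
        medians = [
            np.median(spatial_shuffle_null(m, g, 300, seed=5)) for m in (5, 50, 200)
        ]
        assert medians[0] <= medians[1] <= medians[2]


class TestDecision:
    def test_large_observed_cluster_significant(self, small_grid):
        clusters = find_clusters(
            np.ones(small_grid.n_sources, bool), small_grid
        )  # one giant cluster
        rep = significant_clusters(clusters, np.full(1000, 10))
        assert rep.clusters[0].significant

    def test_cluster_equal_to_threshold_not_significant(self):
        """Strict decision rule: a cluster whose size ties the 95th
        percentile of the null is NOT significant."""
        from seqrecog.cluster import Cluster

        null = np.arange(1, 101)  # nearest-rank 95th percentile = 95
        rep = significant_clusters(
            [Cluster(voxel_ids=np.arange(95), size=95),
             Cluster(voxel_ids=np.arange(96), size=96)],
            null,
        )
        assert rep.threshold_size == 95
        by_size = {c.size: c.significant for c in rep.clusters}
        assert by_size == {96: True, 95: False}

    def test_empty_cluster_list_gives_empty_report(self):
        rep = significant_clusters([], np.zeros(100, int))
        assert rep.clusters == [] and rep.significant_clusters == []

    def test_nearest_rank_percentile_definition(self):
        assert nearest_rank_percentile(np.arange(1, 101), 0.95) == 95
        assert nearest_rank_percentile(np.array([3, 1, 2]), 0.95) == 3


class TestRunMcs:
    def test_same_seed_reproduces_report(self, small_grid, rng):
        v = rng.standard_normal(small_grid.n_sources) * 2
        sm = _tmap(v, df=29)
        a = run_mcs(sm, small_grid, alpha=0.05, n_permutations=200, seed=9)
        b = run_mcs(sm, small_grid, alpha=0.05, n_permutations=200, seed=9)
        for sign in ("positive", "negative"):
            assert np.array_equal(a[sign].null_max_sizes, b[sign].null_max_sizes)
            assert [c.size for c in a[sign].clusters] == [c.size for c in b[sign].clusters]
            assert [c.significant for c in a[sign].clusters] == [
                c.significant for c in b[sign].clusters
            ]

    def test_cluster_sizes_partition_mask_count(self, small_grid, rng):
        v = rng.standard_normal(small_grid.n_sources) * 3
        sm = _tmap(v, df=29)
        reports = run_mcs(sm, small_grid, alpha=0.05, n_permutations=50, seed=1)
        pos, neg = threshold_map(sm, 0.05)
        for mask, rep in ((pos, reports["positive"]), (neg, reports["negative"])):
            sizes = [c.size for c in rep.clusters]
            assert sum(sizes) == mask.count
            all_vox = np.concatenate([c.voxel_ids for c in rep.clusters]) if sizes else []
            assert len(set(map(int, all_vox))) == mask.count

    def test_connectivity_monotonicity_of_cluster_count(self, rng):
        mask = rng.random(1000) < 0.15
        g26 = make_grid((10, 10, 10), connectivity=26)
        g6 = make_grid((10, 10, 10), connectivity=6)
        assert len(find_clusters(mask, g26)) <= len(find_clusters(mask, g6))
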