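"""Tanimoto similarity, silhouette auto-cut clustering with fallbacks,
break-gap scanning, diversity, rank correlations, and heat-map ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from masldscreen.chemspace import (
    break_gap_grid, break_gap_scan, cluster_moa, cluster_structural,
    diversity_index, heatmap_order, medoids_of, partition_silhouette,
    tanimoto, tanimoto_matrix, target_rank_correlations,
)


def _fp(bits_on, size=64):
    v = np.zeros(size, dtype=np.uint8)
    v[list(bits_on)] = 1
    return v


class TestTanimoto:
    def test_identical_nonempty(self):
        assert tanimoto(_fp([1, 5, 9]), _fp([1, 5, 9])) == 1.0

    def test_disjoint(self):
        assert tanimoto(_fp([0, 1]), _fp([2, 3])) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(_fp([1, 2, 3]), _fp([2, 3, 4])) == 0.5

    def test_both_empty_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto(_fp([]), _fp([])) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            tanimoto(_fp([1], size=32), _fp([1], size=64))

    def test_matrix_agrees_with_pairwise(self, rng):
        fps = (rng.random((6, 32)) > 0.6).astype(np.uint8)
        T = tanimoto_matrix(fps)
        for i in range(6):
            for j in range(6):
                if fps[i].any() or fps[j].any():
                    assert T[i, j] == pytest.approx(tanimoto(fps[i], fps[j]))


class TestStructuralClustering:
    def test_two_disjoint_groups(self):
        fps = [_fp([0, 1, 2])] * 4 + [_fp([10, 11, 12])] * 4
        sol = cluster_structural(np.vstack(fps))
        assert sol.n_clusters == 2
        assert sol.silhouette == pytest.approx(1.0)
        assert sol.method == "auto_cut"

    def test_all_identical_engages_fallback(self):
        fps = np.vstack([_fp([3, 4])] * 6)
        sol = cluster_structural(fps)
        assert sol.n_clusters == 1
        assert sol.method != "auto_cut"

    def test_threshold_equals_bruteforce_argmax(self, rng):
        # 8 points, 2 planted blobs; oracle recomputes the grid exhaustively
        base_a, base_b = _fp(range(0, 12)), _fp(range(20, 32))
        fps = []
        for base in (base_a, base_b):
            for _ in range(4):
                v = base.copy()
                flip = rng.integers(0, 64, size=2)
                v[flip] ^= 1
                fps.append(v)
        fps = np.vstack(fps)
        grid = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
        sol = cluster_structural(fps, grid=grid)

        D = 1.0 - tanimoto_matrix(fps)
        np.fill_diagonal(D, 0.0)
        best_thr, best_sil = None, -np.inf
        for thr in grid:
            Z = linkage(squareform(D, checks=False), method="single")
            labels = fcluster(Z, t=thr, criterion="distance") - 1
            k = np.unique(labels).size
            if k <= 1 or k >= len(labels):
                sil = -1.0
            else:
                vals = silhouette_samples(D, labels, metric="precomputed")
                counts = np.bincount(labels)
                vals = np.where(counts[labels] == 1, 0.0, vals)
                sil = vals.mean()
            if sil > best_sil:
                best_thr, best_sil = thr, sil
        assert sol.method == "auto_cut"
        assert sol.threshold == best_thr
        assert sol.silhouette == pytest.approx(best_sil)

    def test_assignments_partition_pool(self, rng):
        fps = (rng.random((15, 64)) > 0.7).astype(np.uint8)
        fps[fps.sum(axis=1) == 0, 0] = 1
        sol = cluster_structural(fps)
        assert sol.assignments.shape == (15,)
        assert sum(sol.sizes) == 15

    def test_medoid_minimizes_intra_cluster_distance(self, rng):
        D = rng.random((8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        meds = medoids_of(D, labels)
        for c, med in enumerate(meds):
            members = np.flatnonzero(labels == c)
            sums = D[np.ix_(members, members)].sum(axis=1)
            assert D[med, members].sum() == pytest.approx(sums.min())

    def test_singleton_pool_trivial(self):
        sol = cluster_structural(np.vstack([_fp([1])]))
        assert sol.method == "trivial"
        assert sol.n_clusters == 1


class TestMoaClustering:
    def test_orthogonal_profiles_two_clusters(self):
        P = np.array([[0.9, 0.8, 0, 0], [0.8, 0.9, 0, 0],
                      [0, 0, 0.9, 0.8], [0, 0, 0.8, 0.9]])
        sol, keep = cluster_moa(P)
        assert keep.all()
        assert sol.n_clusters == 2

    def test_proportional_vectors_cluster_together(self):
        P = np.array([[0.1, 0.2, 0.3], [0.2, 0.4, 0.6], [0.9, 0.1, 0.0]])
        sol, _ = cluster_moa(P)
        assert sol.assignments[0] == sol.assignments[1]
        assert sol.assignments[0] != sol.assignments[2]

    def test_zero_rows_excluded_with_warning(self):
        P = np.array([[0.9, 0.1], [0.0, 0.0], [0.1, 0.9]])
        with pytest.warns(UserWarning, match="zero probability"):
            sol, keep = cluster_moa(P)
        assert list(keep) == [True, False, True]
        assert sol.assignments.shape == (2,)

    def test_planted_archetypes_recovered(self, rng):
        # 30 compounds from 3 orthogonal MOA archetypes plus small noise
        archetypes = np.array([[0.9, 0.9, 0.05, 0.05, 0.05],
                               [0.05, 0.05, 0.9, 0.9, 0.05],
                               [0.05, 0.05, 0.05, 0.05, 0.9]])
        labels_true = np.repeat([0, 1, 2], 10)
        P = archetypes[labels_true] + rng.normal(0, 0.02, size=(30, 5))
        P = np.clip(P, 0.01, 1)
        sol, _ = cluster_moa(P)
        assert sol.n_clusters == 3
        # planted labels must align exactly up to relabeling
        mapping = {}
        for pred, true in zip(sol.assignments, labels_true):
            mapping.setdefault(pred, true)
            assert mapping[pred] == true


class TestDiversityAndBreaks:
    def test_diversity_identical_zero(self):
        assert diversity_index(np.vstack([_fp([1, 2])] * 5)) == 0.0

    def test_diversity_disjoint_one(self):
        fps = np.vstack([_fp([0]), _fp([1]), _fp([2])])
        assert diversity_index(fps) == 1.0

    def test_diversity_mixed(self):
        fps = np.vstack([_fp([1, 2]), _fp([1, 2]), _fp([40, 41])])
        assert diversity_index(fps) == pytest.approx(2 / 3)

    def _frame(self, P, ids=None):
        ids = ids or [f"c{i}" for i in range(len(P))]
        return pd.DataFrame(P, index=ids, columns=["T0", "T1"])

    def test_flags_similar_pair_with_gap(self):
        fps = np.vstack([_fp(range(10)), _fp(range(9))])  # T = 0.9
        P = self._frame([[0.9, 0.2], [0.4, 0.2]])
        out = break_gap_scan(fps, P)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["target"] == "T0"
        assert row["delta_p"] == pytest.approx(0.5)
        assert row["tanimoto"] == pytest.approx(0.9)

    def test_dissimilar_pair_not_flagged(self):
        fps = np.vstack([_fp(range(10)), _fp(range(7))])  # T = 0.7
        P = self._frame([[0.9, 0.2], [0.4, 0.2]])
        assert break_gap_scan(fps, P).empty

    def test_relaxing_gap_threshold_monotone(self, rng):
        fps = (rng.random((10, 64)) > 0.5).astype(np.uint8)
        P = self._frame(rng.random((10, 2)))
        n_40 = len(break_gap_scan(fps, P, tan_thr=0.3, gap_thr=0.40))
        n_30 = len(break_gap_scan(fps, P, tan_thr=0.3, gap_thr=0.30))
        assert n_30 >= n_40

    def test_grid_counts_shape(self, rng):
        fps = (rng.random((6, 64)) > 0.5).astype(np.uint8)
        P = self._frame(rng.random((6, 2)))
        grid = break_gap_grid(fps, P)
        assert len(grid) == 9
        assert set(grid.columns) == {"tan_thr", "gap_thr", "n_flagged"}


class TestRankCorrelations:
    def test_duplicated_column_correlation_one(self):
        P = pd.DataFrame({"a": [0.1, 0.5, 0.9, 0.3],
                          "b": [0.1, 0.5, 0.9, 0.3]})
        assert target_rank_correlations(P).loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self):
        P = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.9, 0.5, 0.1]})
        assert target_rank_correlations(P).loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        # ranks x: 1..5, ranks y: (2,1,4,3,5); d^2 sum = 4
        # rho = 1 - 6*4 / (5*24) = 0.8
        P = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.4, 0.5],
                          "b": [0.15, 0.1, 0.4, 0.3, 0.9]})
        assert target_rank_correlations(P).loc["a", "b"] == pytest.approx(0.8)

    def test_constant_column_missing(self):
        P = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.2, 0.2, 0.2]})
        assert np.isnan(target_rank_correlations(P).loc["a", "b"])


class TestHeatmapOrder:
    def test_cluster_then_weighted_ordering(self):
        hits = pd.DataFrame({
            "compound_id": ["a", "b", "c", "d"],
            "cluster_id": [1, 0, 0, 1],
            "TA_weighted": [0.9, 0.2, 0.8, 0.1],
            "main_score": [0.9, 0.2, 0.8, 0.1],
        })
        assert heatmap_order(hits) == ["c", "b", "a", "d"]

    def test_full_ties_stable(self):
        hits = pd.DataFrame({
            "compound_id": ["x", "y", "z"],
            "cluster_id": [0, 0, 0],
            "TA_weighted": [0.5] * 3,
            "main_score": [0.5] * 3,
        })
        assert heatmap_order(hits) == ["x", "y", "z"]
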