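"""Chemical-space and mechanism-of-action structure: Tanimoto similarity,
silhouette-driven auto-cut clustering with kNN/MST fallbacks, break-gap
(activity-cliff) scanning, target co-activation correlations, an integral
diversity index, and heat-map column ordering.

Structural clustering operates on 1 - Tanimoto distances over Morgan bit
fingerprints, scanning a threshold grid (0.10-0.40 by default) and keeping
the cut that maximizes the silhouette score.  Degenerate grids (every cut
producing one giant cluster or all singletons) fall back, in order, to a
threshold shift toward maximum similarity, mutual-kNN communities, and an
MST largest-gap cut.  MOA clustering reuses the same machinery on cosine
distances between per-target probability vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_samples


@dataclass
class ClusterSolution:
    assignments: np.ndarray          # cluster id per compound, 0-based
    threshold: float | None
    method: str                      # auto_cut | threshold_shift | knn_fallback | mst_cut | trivial
    silhouette: float
    medoids: np.ndarray = field(default=None)

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1 if self.assignments.size else 0

    @property
    def sizes(self) -> list[int]:
        return sorted(np.bincount(self.assignments).tolist(), reverse=True)


def tanimoto(fp_a, fp_b) -> float:
    """|a AND b| / |a OR b| on equal-length bit vectors; both-empty -> 0."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(fps) -> np.ndarray:
    F = np.asarray(fps, dtype=np.float64)
    inter = F @ F.T
    pop = F.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(T, 1.0)
    return T


def cosine_matrix(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    norms = np.linalg.norm(P, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero probability rows must be excluded first")
    S = (P @ P.T) / np.outer(norms, norms)
    return np.clip(S, -1.0, 1.0)


def partition_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette on a precomputed distance matrix; singletons
    contribute 0, and k=1 or k=n partitions score -1 so the grid search
    avoids degenerate cuts."""
    n = len(labels)
    k = np.unique(labels).size
    if k <= 1 or k >= n:
        return -1.0
    vals = silhouette_samples(D, labels, metric="precomputed")
    counts = np.bincount(labels)
    vals = np.where(counts[labels] == 1, 0.0, vals)
    return float(vals.mean())


def _cut_at(D, threshold: float, method_linkage: str) -> np.ndarray:
    Z = linkage(squareform(D, checks=False), method=method_linkage)
    labels = fcluster(Z, t=threshold, criterion="distance")
    return labels - 1


def medoids_of(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One medoid per cluster: member minimizing summed intra-cluster
    distance (lowest index on ties)."""
    meds = []
    for c in range(int(labels.max()) + 1):
        members = np.flatnonzero(labels == c)
        sums = D[np.ix_(members, members)].sum(axis=1)
        meds.append(int(members[int(np.argmin(sums))]))
    return np.array(meds)


def _knn_communities(D: np.ndarray, k: int = 5) -> np.ndarray:
    """Mutual-kNN graph; connected components as clusters."""
    n = D.shape[0]
    k = min(k, n - 1)
    order = np.argsort(D, axis=1, kind="stable")
    neigh = [set(j for j in row if j != i)for i, row in enumerate(order)]
    neigh = [set(list(sorted(s, key=lambda j: (D[i, j], j)))[:k])
             for i, s in enumerate(neigh)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in neigh[i]:
            if i in neigh[j]:
                g.add_edge(i, int(j))
    labels = np.empty(n, dtype=int)
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        labels[list(comp)] = cid
    return labels


def _mst_cut(D: np.ndarray) -> np.ndarray:
    """Remove the single largest-weight edge of the minimum spanning tree."""
    mst = minimum_spanning_tree(D).tocoo()
    if mst.nnz == 0:
        return np.zeros(D.shape[0], dtype=int)
    imax = int(np.argmax(mst.data))
    g = nx.Graph()
    g.add_nodes_from(range(D.shape[0]))
    for e, (i, j) in enumerate(zip(mst.row, mst.col)):
        if e != imax:
            g.add_edge(int(i), int(j))
    labels = np.empty(D.shape[0], dtype=int)
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        labels[list(comp)] = cid
    return labels


def cluster_distance_matrix(D: np.ndarray, grid, linkage_method: str = "single",
                            knn_k: int = 5) -> ClusterSolution:
    """Silhouette auto-cut over a threshold grid with ordered fallbacks."""
    n = D.shape[0]
    if n < 2:
        return ClusterSolution(assignments=np.zeros(n, dtype=int),
                               threshold=None, method="trivial",
                               silhouette=0.0,
                               medoids=np.arange(n))
    best = None
    for thr in grid:
        labels = _cut_at(D, thr, linkage_method)
        sil = partition_silhouette(D, labels)
        if best is None or sil > best[1]:
            best = (labels, sil, thr)
    labels, sil, thr = best
    method = "auto_cut"
    if sil <= -1.0:  # every grid cut degenerate
        # fallback 1: shift the threshold toward maximum similarity
        offdiag = D[np.triu_indices(n, 1)]
        shifted = float(np.quantile(offdiag[offdiag > 0], 0.05)) \
            if np.any(offdiag > 0) else 0.0
        if shifted > 0:
            labels2 = _cut_at(D, shifted, linkage_method)
            sil2 = partition_silhouette(D, labels2)
            if sil2 > -1.0:
                labels, sil, thr, method = labels2, sil2, shifted, "threshold_shift"
        if method == "auto_cut":
            # fallback 2: mutual-kNN communities
            labels2 = _knn_communities(D, k=knn_k)
            sil2 = partition_silhouette(D, labels2)
            if sil2 > -1.0:
                labels, sil, thr, method = labels2, sil2, None, "knn_fallback"
            else:
                # fallback 3: MST largest-gap cut
                labels2 = _mst_cut(D)
                labels, thr, method = labels2, None, "mst_cut"
                sil = partition_silhouette(D, labels2)
    labels = _canonical_labels(labels)
    return ClusterSolution(assignments=labels, threshold=thr, method=method,
                           silhouette=sil, medoids=medoids_of(D, labels))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance for deterministic ids."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_structural(fps, grid=(0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40),
                       linkage_method: str = "single",
                       knn_k: int = 5) -> ClusterSolution:
    """Structural clustering on 1 - Tanimoto distances with auto-cut."""
    D = 1.0 - tanimoto_matrix(fps)
    np.fill_diagonal(D, 0.0)
    return cluster_distance_matrix(D, grid, linkage_method, knn_k)


def cluster_moa(p_matrix, grid=None, linkage_method: str = "single",
                knn_k: int = 5) -> tuple[ClusterSolution, np.ndarray]:
    """MOA clustering of per-target probability vectors on cosine distance.

    Zero rows are excluded with a warning; returns (solution over the kept
    rows, boolean keep mask aligned with the input).
    """
    P = np.asarray(p_matrix, dtype=float)
    keep = np.linalg.norm(P, axis=1) > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero probability rows excluded "
                      "from MOA clustering")
    if grid is None:
        grid = np.round(np.arange(0.05, 0.501, 0.05), 3)
    D = 1.0 - cosine_matrix(P[keep])
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return cluster_distance_matrix(D, grid, linkage_method, knn_k), keep


def diversity_index(fps) -> float:
    """Integral diversity: 1 - mean pairwise Tanimoto over all pairs."""
    T = tanimoto_matrix(fps)
    n = T.shape[0]
    if n < 2:
        raise ValueError("need at least two fingerprints")
    pairs = T[np.triu_indices(n, 1)]
    return float(1.0 - pairs.mean())


def break_gap_scan(fps, p_matrix: pd.DataFrame, tan_thr: float = 0.80,
                   gap_thr: float = 0.40) -> pd.DataFrame:
    """Activity-cliff scan: all (pair, target) with Tanimoto >= tan_thr and
    |p_i - p_j| >= gap_thr."""
    T = tanimoto_matrix(fps)
    ids = list(p_matrix.index)
    P = p_matrix.to_numpy(dtype=float)
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if T[i, j] < tan_thr:
                continue
            for t_idx, target in enumerate(p_matrix.columns):
                delta = abs(P[i, t_idx] - P[j, t_idx])
                if delta >= gap_thr:
                    rows.append({"id_a": ids[i], "id_b": ids[j],
                                 "tanimoto": T[i, j], "target": target,
                                 "p_a": P[i, t_idx], "p_b": P[j, t_idx],
                                 "delta_p": delta})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "tanimoto", "target",
                                       "p_a", "p_b", "delta_p"])


def break_gap_grid(fps, p_matrix: pd.DataFrame,
                   tan_grid=(0.75, 0.80, 0.85),
                   gap_grid=(0.30, 0.40, 0.50)) -> pd.DataFrame:
    """Per-cell flagged-pair counts over the 3x3 threshold grid."""
    rows = []
    for t in tan_grid:
        for g in gap_grid:
            hits = break_gap_scan(fps, p_matrix, t, g)
            rows.append({"tan_thr": t, "gap_thr": g, "n_flagged": len(hits)})
    return pd.DataFrame(rows)


def target_rank_correlations(p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation per target pair; constant columns yield
    missing entries."""
    if len(p_matrix) < 3:
        raise ValueError("need at least 3 compounds")
    cols = list(p_matrix.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x = p_matrix[cols[i]].to_numpy(dtype=float)
            y = p_matrix[cols[j]].to_numpy(dtype=float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                rho = np.nan
            else:
                rho = spearmanr(x, y).statistic
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def heatmap_order(hits: pd.DataFrame) -> list:
    """Column order for the probabilistic heat map: cluster_id ascending,
    TA_weighted descending, main_score descending; stable."""
    ordered = hits.sort_values(
        by=["cluster_id", "TA_weighted", "main_score"],
        ascending=[True, False, False], kind="stable")
    return list(ordered["compound_id"])


def cluster_table(ids, structural: ClusterSolution,
                  moa: ClusterSolution | None = None,
                  moa_mask=None) -> pd.DataFrame:
    df = pd.DataFrame({"compound_id": list(ids),
                       "cluster_id": structural.assignments})
    df["is_medoid"] = [i in set(structural.medoids) for i in range(len(df))]
    if moa is not None:
        moa_col = np.full(len(df), -1)
        idx = np.flatnonzero(moa_mask) if moa_mask is not None \
            else np.arange(len(df))
        moa_col[idx] = moa.assignments
        df["moa_cluster_id"] = moa_col
    return df
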