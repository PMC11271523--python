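"""Spatial statistics: duct distances, neighborhood composition, the 8x8
co-localization matrix, and its within-sample permutation null.

Distances to ducts follow the centroid-to-nearest-in-duct-cell convention
with a natural-log transform; a transformed value v converts to micrometers
as exp(v) * pixel_size_um (0.18 um/px by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

N_CLUSTERS = 8
DEFAULT_RADIUS_UM = 25.9
DEFAULT_PIXEL_SIZE_UM = 0.18


@dataclass
class DuctDistance:
    """Per-cell raw pixel distance to the nearest in-duct cell and its
    natural-log transform (0 for in-duct cells and distances <= 1 px)."""

    raw_px: np.ndarray
    transformed: np.ndarray
    missing: np.ndarray  # true where no in-duct reference cell existed
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def to_um(self) -> np.ndarray:
        return np.exp(self.transformed) * self.pixel_size_um


@dataclass
class ColocalizationMatrix:
    """Row-stochastic neighborhood-composition matrix for one sample."""

    matrix: np.ndarray  # (8, 8); NaN rows where no eligible focal cells
    radius_um: float
    cell_density: float  # cells per um^2
    sample_id: str = ""
    focal_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CLUSTERS, dtype=int)
    )
    n_excluded: int = 0  # zero-neighbor cells excluded from averaging

    @property
    def defined_rows(self) -> np.ndarray:
        return ~np.isnan(self.matrix).all(axis=1)


@dataclass
class PermutationNull:
    null_mean: np.ndarray
    n_shuffles: int
    seed: int
    fold_change: np.ndarray
    log2_fold_change: np.ndarray


def transform_distance(raw_px: np.ndarray) -> np.ndarray:
    """ln of the pixel distance, floored at 0 (covers in-duct and <=1 px)."""
    raw = np.asarray(raw_px, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(raw > 1.0, np.log(raw), 0.0)


def duct_distance(
    centroids: np.ndarray,
    inside_duct: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> DuctDistance:
    """Distance of each cell to the nearest in-duct cell centroid.

    In-duct cells get raw and transformed distance 0. If no in-duct cells
    exist, out-of-duct distances are flagged missing (NaN), not 0.
    """
    centroids = np.asarray(centroids, dtype=float)
    inside = np.asarray(inside_duct, dtype=bool)
    n = len(centroids)
    raw = np.zeros(n)
    missing = np.zeros(n, dtype=bool)
    out_idx = np.flatnonzero(~inside)
    if out_idx.size:
        if inside.any():
            tree = cKDTree(centroids[inside])
            d, _ = tree.query(centroids[out_idx])
            raw[out_idx] = d
        else:
            raw[out_idx] = np.nan
            missing[out_idx] = True
    transformed = np.where(missing, np.nan, transform_distance(np.nan_to_num(raw)))
    return DuctDistance(
        raw_px=raw, transformed=transformed, missing=missing, pixel_size_um=pixel_size_um
    )


def neighborhood_counts(
    centroids: np.ndarray,
    labels: np.ndarray,
    radius_um: float = DEFAULT_RADIUS_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    n_clusters: int = N_CLUSTERS,
) -> np.ndarray:
    """Per-cell counts of neighbors of each cluster within ``radius_um``.

    The focal cell is excluded from its own neighborhood. Implemented with a
    k-d tree; tests verify equality with the O(n^2) scan.
    """
    centroids = np.asarray(centroids, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= n_clusters:
        raise ValueError(f"labels must be in 0..{n_clusters - 1}")
    radius_px = radius_um / pixel_size_um
    n = len(centroids)
    counts = np.zeros((n, n_clusters), dtype=int)
    if n == 0:
        return counts
    tree = cKDTree(centroids)
    for i, nbrs in enumerate(tree.query_ball_point(centroids, radius_px)):
        for j in nbrs:
            if j != i:
                counts[i, labels[j]] += 1
    return counts


def neighborhood_counts_bruteforce(
    centroids, labels, radius_um=DEFAULT_RADIUS_UM,
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM, n_clusters=N_CLUSTERS,
) -> np.ndarray:
    """O(n^2) reference implementation (oracle for the k-d tree version)."""
    centroids = np.asarray(centroids, dtype=float)
    labels = np.asarray(labels, dtype=int)
    radius_px = radius_um / pixel_size_um
    n = len(centroids)
    counts = np.zeros((n, n_clusters), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(*(centroids[i] - centroids[j])) <= radius_px:
                counts[i, labels[j]] += 1
    return counts


def coloc_matrix(
    counts: np.ndarray,
    labels: np.ndarray,
    radius_um: float = DEFAULT_RADIUS_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    area_px2: float | None = None,
    sample_id: str = "",
    n_clusters: int = N_CLUSTERS,
) -> ColocalizationMatrix:
    """Average neighborhood cluster proportions around cells of each cluster.

    Cells with zero neighbors are excluded from the averaging (and tallied);
    rows with no eligible focal cells are NaN.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    totals = counts.sum(axis=1)
    eligible = totals > 0
    props = np.zeros_like(counts)
    props[eligible] = counts[eligible] / totals[eligible, None]

    matrix = np.full((n_clusters, n_clusters), np.nan)
    focal_counts = np.zeros(n_clusters, dtype=int)
    for c in range(n_clusters):
        sel = (labels == c) & eligible
        focal_counts[c] = int(sel.sum())
        if focal_counts[c]:
            matrix[c] = props[sel].mean(axis=0)
    if area_px2 is not None and area_px2 > 0:
        density = len(labels) / (area_px2 * pixel_size_um**2)
    else:
        density = np.nan
    return ColocalizationMatrix(
        matrix=matrix,
        radius_um=radius_um,
        cell_density=float(density),
        sample_id=sample_id,
        focal_counts=focal_counts,
        n_excluded=int((~eligible).sum()),
    )


def permutation_null(
    centroids: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 2000,
    seed: int = 0,
    radius_um: float = DEFAULT_RADIUS_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    n_clusters: int = N_CLUSTERS,
) -> PermutationNull:
    """Within-sample label-shuffle null for the co-localization matrix.

    Geometry (the neighbor graph) stays fixed; only labels permute, so the
    neighbor index lists are computed once. Fold change is observed / null
    mean elementwise, NaN where the null entry is undefined or 0.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters present for a permutation null")
    rng = np.random.default_rng(seed)
    counts = neighborhood_counts(
        centroids, labels, radius_um, pixel_size_um, n_clusters
    )
    observed = coloc_matrix(
        counts, labels, radius_um, pixel_size_um, n_clusters=n_clusters
    ).matrix

    # fixed geometry: flat directed edge arrays (focal -> neighbor)
    tree = cKDTree(np.asarray(centroids, dtype=float))
    nbrs = tree.query_ball_point(
        np.asarray(centroids, dtype=float), radius_um / pixel_size_um
    )
    n = len(labels)
    edge_i = np.concatenate(
        [np.full(len(lst) - (i in lst), i, dtype=np.int64) for i, lst in enumerate(nbrs)]
    ) if n else np.zeros(0, dtype=np.int64)
    edge_j = np.concatenate(
        [np.array([j for j in lst if j != i], dtype=np.int64) for i, lst in enumerate(nbrs)]
    ) if n else np.zeros(0, dtype=np.int64)
    degree = np.bincount(edge_i, minlength=n).astype(float)
    eligible = degree > 0

    acc = np.zeros((n_clusters, n_clusters))
    cnt = np.zeros((n_clusters, n_clusters))
    perm_labels = labels.copy()
    for _ in range(n_shuffles):
        rng.shuffle(perm_labels)
        m = _coloc_from_edges(
            perm_labels, edge_i, edge_j, degree, eligible, n_clusters
        )
        ok = ~np.isnan(m)
        acc[ok] += m[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        null_mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        fold = observed / null_mean
        log2fc = np.log2(fold)
    return PermutationNull(
        null_mean=null_mean,
        n_shuffles=n_shuffles,
        seed=seed,
        fold_change=fold,
        log2_fold_change=log2fc,
    )


def _coloc_from_edges(labels, edge_i, edge_j, degree, eligible, n_clusters):
    """One co-localization matrix from precomputed neighbor edges (no loops
    over cells: bincount over edges, then per-cluster row means)."""
    n = len(labels)
    counts = np.bincount(
        edge_i * n_clusters + labels[edge_j], minlength=n * n_clusters
    ).reshape(n, n_clusters).astype(float)
    props = counts / np.maximum(degree, 1.0)[:, None]
    matrix = np.full((n_clusters, n_clusters), np.nan)
    for c in range(n_clusters):
        sel = (labels == c) & eligible
        if sel.any():
            matrix[c] = props[sel].mean(axis=0)
    return matrix


def sample_representation(
    matrix: ColocalizationMatrix,
    cluster_proportions: np.ndarray | None = None,
    mode: str = "coloc",
    ablate: int | None = None,
) -> np.ndarray:
    """Flatten a co-localization matrix into a classifier input vector.

    Undefined (NaN) rows are imputed with the sample's global cluster
    proportions when available, else with the uniform vector. ``mode`` is one
    of ``coloc`` (matrix + density), ``props`` (cluster proportions +
    density), or ``both``. ``ablate=k`` drops row/column k (7x7 variant).
    """
    m = matrix.matrix.copy()
    k = m.shape[0]
    if cluster_proportions is None:
        fill = np.full(k, 1.0 / k)
    else:
        fill = np.asarray(cluster_proportions, dtype=float)
    for row in range(k):
        if np.isnan(m[row]).all():
            m[row] = fill
    density = matrix.cell_density if np.isfinite(matrix.cell_density) else 0.0
    if ablate is not None:
        keep = [i for i in range(k) if i != ablate]
        m = m[np.ix_(keep, keep)]
        # re-normalize rows after ablation
        s = m.sum(axis=1, keepdims=True)
        m = np.divide(m, s, out=np.full_like(m, 1.0 / max(k - 1, 1)), where=s > 0)
        props_vec = None if cluster_proportions is None else fill[keep]
    else:
        props_vec = None if cluster_proportions is None else fill
    if mode == "coloc":
        return np.concatenate([m.ravel(), [density]])
    if props_vec is None:
        raise ValueError("cluster_proportions required for mode 'props'/'both'")
    if mode == "props":
        return np.concatenate([props_vec, [density]])
    if mode == "both":
        return np.concatenate([m.ravel(), props_vec, [density]])
    raise ValueError(f"unknown representation mode: {mode}")
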