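"""Cell-state derivation: balanced downsampling, PCA + mini-batch k-means
top-level clustering into 8 states, inertia-guided subclustering, held-out
assignment, and composition summaries.

Cluster ids are relabeled canonically after fitting (by ascending mean
nucleus area when areas are supplied, else by the first principal component
of the centroids), since raw k-means ids are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.decomposition import PCA

N_TOP_CLUSTERS = 8


@dataclass
class SubclusterModel:
    kmeans: KMeans | None  # None when the cluster stayed whole
    n_subclusters: int
    inertia_curve: dict[int, float]
    decision_trace: list[str] = field(default_factory=list)


@dataclass
class ClusteringModel:
    pca: PCA
    kmeans: MiniBatchKMeans
    relabel: np.ndarray  # raw k-means id -> canonical id
    seed: int
    n_fitted: int
    subclusters: dict[int, SubclusterModel] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.kmeans.n_clusters


@dataclass
class CompositionTable:
    table: pd.DataFrame  # categories (rows) x clusters (columns)
    normalize_axis: str  # "column", "row", or "none"


def balanced_downsample(
    cell_index: np.ndarray,
    categories: np.ndarray,
    per_category_n: int,
    seed: int = 0,
) -> np.ndarray:
    """Sample exactly ``per_category_n`` cells from each category without
    replacement; returns the selected entries of ``cell_index``."""
    cell_index = np.asarray(cell_index)
    categories = np.asarray(categories)
    rng = np.random.default_rng(seed)
    chosen = []
    for cat in np.unique(categories):
        idx = np.flatnonzero(categories == cat)
        if len(idx) < per_category_n:
            raise ValueError(
                f"category {cat!r} has only {len(idx)} cells (< {per_category_n})"
            )
        chosen.append(rng.choice(idx, size=per_category_n, replace=False))
    return cell_index[np.sort(np.concatenate(chosen))]


def fit_topclusters(
    latents: np.ndarray,
    k: int = N_TOP_CLUSTERS,
    n_components: int = 50,
    seed: int = 0,
    areas: np.ndarray | None = None,
    n_restarts: int = 3,
) -> ClusteringModel:
    """PCA to min(n_components, dim) then mini-batch k-means with restarts.

    ``areas`` (per-cell nucleus areas) drive the canonical relabeling:
    cluster 0 = smallest mean area, k-1 = largest.
    """
    latents = np.asarray(latents, dtype=float)
    n, d = latents.shape
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    n_components = min(n_components, d, n)
    pca = PCA(n_components=n_components, random_state=seed)
    reduced = pca.fit_transform(latents)
    km = MiniBatchKMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        batch_size=max(256, 3 * k),
    ).fit(reduced)
    raw = km.labels_
    if areas is not None:
        order_stat = np.array(
            [np.mean(np.asarray(areas)[raw == c]) for c in range(k)]
        )
    else:
        order_stat = km.cluster_centers_[:, 0]
    order = np.argsort(order_stat)  # canonical position of each rank
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusteringModel(
        pca=pca, kmeans=km, relabel=relabel, seed=seed, n_fitted=n
    )


def assign(model: ClusteringModel, latents: np.ndarray) -> np.ndarray:
    """Deterministic nearest-centroid assignment in PCA space, canonical ids."""
    latents = np.asarray(latents, dtype=float)
    if latents.shape[1] != model.pca.n_features_in_:
        raise ValueError(
            f"latent dim {latents.shape[1]} != fitted dim {model.pca.n_features_in_}"
        )
    raw = model.kmeans.predict(model.pca.transform(latents))
    return model.relabel[raw]


def assign_subclusters(
    model: ClusteringModel, latents: np.ndarray, labels: np.ndarray | None = None
) -> np.ndarray:
    """Subcluster labels (0-based within each top cluster; 0 when unsplit)."""
    if labels is None:
        labels = assign(model, latents)
    reduced = model.pca.transform(np.asarray(latents, dtype=float))
    sub = np.zeros(len(labels), dtype=int)
    for c, sm in model.subclusters.items():
        sel = labels == c
        if sm.kmeans is not None and sel.any():
            sub[sel] = sm.kmeans.predict(reduced[sel])
    return sub


def _tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def _category_composition(categories: np.ndarray, sel: np.ndarray, cats) -> np.ndarray:
    counts = np.array([(categories[sel] == c).sum() for c in cats], dtype=float)
    total = counts.sum()
    return counts / total if total else counts


def fit_subclusters(
    model: ClusteringModel,
    latents: np.ndarray,
    categories: np.ndarray,
    cluster_id: int,
    candidate_ks: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    tau: float = 0.1,
    seed: int | None = None,
) -> SubclusterModel:
    """Inertia-elbow subcluster count, then decrement while any two sibling
    subclusters have near-identical category composition (TV distance < tau).
    """
    labels = assign(model, latents)
    sel = labels == cluster_id
    if not sel.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    reduced = model.pca.transform(np.asarray(latents, dtype=float))[sel]
    cats_here = np.asarray(categories)[sel]
    ks = sorted(set(candidate_ks))
    if max(ks) > len(reduced):
        raise ValueError("cluster smaller than the largest candidate k")
    seed = model.seed if seed is None else seed
    trace: list[str] = []

    inertia: dict[int, float] = {}
    models: dict[int, KMeans | None] = {}
    for k in ks:
        if k == 1:
            center = reduced.mean(axis=0)
            inertia[1] = float(((reduced - center) ** 2).sum())
            models[1] = None
        else:
            km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(reduced)
            inertia[k] = float(km.inertia_)
            models[k] = km

    # initial k: sharpest relative inertia decrease between consecutive ks
    ks_arr = np.array(ks)
    rel_drop = {}
    for a, b in zip(ks_arr[:-1], ks_arr[1:]):
        rel_drop[int(b)] = (inertia[int(a)] - inertia[int(b)]) / max(inertia[int(a)], 1e-12)
    k_init = max(rel_drop, key=rel_drop.get) if rel_drop else ks[0]
    trace.append(f"inertia elbow suggests k={k_init}")

    cat_values = np.unique(np.asarray(categories))
    k_final = k_init
    while k_final > 1:
        km = models[k_final]
        sub = km.predict(reduced)
        comps = [
            _category_composition(cats_here, sub == j, cat_values)
            for j in range(k_final)
        ]
        redundant = any(
            _tv_distance(comps[i], comps[j]) < tau
            for i in range(k_final)
            for j in range(i + 1, k_final)
        )
        if not redundant:
            break
        trace.append(f"k={k_final}: sibling compositions within tau={tau}; decrement")
        k_final -= 1
        if k_final not in models:
            models[k_final] = (
                None
                if k_final == 1
                else KMeans(n_clusters=k_final, n_init=5, random_state=seed).fit(reduced)
            )
    trace.append(f"final subcluster count {k_final}")
    sub_model = SubclusterModel(
        kmeans=models[k_final],
        n_subclusters=k_final,
        inertia_curve=inertia,
        decision_trace=trace,
    )
    model.subclusters[cluster_id] = sub_model
    return sub_model


def composition(
    labels: np.ndarray,
    categories: np.ndarray,
    normalize_axis: str = "column",
    category_order=None,
    n_clusters: int = N_TOP_CLUSTERS,
) -> CompositionTable:
    """Cross-tabulate category x cluster counts and normalize.

    ``normalize_axis='column'`` makes each cluster column sum to 1;
    ``'row'`` normalizes per category; ``'none'`` returns raw counts.
    """
    labels = np.asarray(labels)
    categories = np.asarray(categories)
    cats = list(category_order) if category_order is not None else sorted(set(categories))
    unknown = set(categories) - set(cats)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    mat = np.zeros((len(cats), n_clusters), dtype=float)
    for i, cat in enumerate(cats):
        sel = categories == cat
        mat[i] = np.bincount(labels[sel], minlength=n_clusters)[:n_clusters]
    if normalize_axis == "column":
        s = mat.sum(axis=0, keepdims=True)
        mat = np.divide(mat, s, out=np.zeros_like(mat), where=s > 0)
    elif normalize_axis == "row":
        s = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, s, out=np.zeros_like(mat), where=s > 0)
    elif normalize_axis != "none":
        raise ValueError("normalize_axis must be 'column', 'row', or 'none'")
    df = pd.DataFrame(mat, index=cats, columns=[f"cluster{c}" for c in range(n_clusters)])
    return CompositionTable(table=df, normalize_axis=normalize_axis)


def umap_embedding(
    latents: np.ndarray, n_neighbors: int = 10, min_dist: float = 0.25, seed: int = 0
) -> np.ndarray:
    """2-D UMAP of latents for visualization only (not used by any analysis
    step). Imported lazily so the heavy dependency stays optional."""
    import umap

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    return reducer.fit_transform(np.asarray(latents, dtype=float))


def centroid_ordering(model: ClusteringModel) -> list[int]:
    """Toy ordering utility: clusters sorted by distance (in PCA space) from
    canonical cluster 0's centroid. Explicitly NOT a trajectory-inference
    method; export latents + labels for external trajectory tools instead.
    """
    centers = model.kmeans.cluster_centers_
    canon = {model.relabel[raw]: centers[raw] for raw in range(model.k)}
    root = canon[0]
    d = {c: float(np.linalg.norm(v - root)) for c, v in canon.items()}
    return sorted(d, key=d.get)
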