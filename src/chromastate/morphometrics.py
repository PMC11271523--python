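"""Interpretable nuclear-morphology and chromatin-organization features,
per-cluster discriminative testing, and correlation-based feature grouping.

The feature set is a documented representative panel (~50 features) covering
size, shape, radius, curvature, image-moment, texture, and intensity
families; names are namespaced (``size.area`` etc.) so the panel can grow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import feature as skfeature
from skimage import filters, measure
from statsmodels.stats.multitest import multipletests

FEATURE_FAMILIES = ("size", "shape", "radius", "curvature", "moments", "texture", "intensity")


class EmptyMaskError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Single-nucleus features


def _boundary_polygon(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    return max(contours, key=len)


def _smooth_closed(poly: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    # wrap-around Gaussian smoothing to suppress pixelation before curvature
    return np.column_stack(
        [ndi.gaussian_filter1d(poly[:, i], sigma=sigma, mode="wrap") for i in range(2)]
    )


def _curvature(poly: np.ndarray) -> np.ndarray:
    d1 = np.gradient(poly, axis=0)
    d2 = np.gradient(d1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(den > 1e-12, num / den, 0.0)
    return k


def compute_features(patch: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Named morphometric features of one masked nucleus patch.

    ``patch`` is the masked intensity image (zeros outside ``mask``).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("empty nucleus mask")
    patch = np.asarray(patch, dtype=np.float64)
    lab = mask.astype(np.uint8)
    prop = measure.regionprops(lab, intensity_image=patch)[0]
    out: dict[str, float] = {}

    # --- size; Crofton perimeter corrects the digitization overestimate
    area = float(prop.area)
    perim = float(prop.perimeter_crofton)
    out["size.area"] = area
    out["size.perimeter"] = perim
    out["size.equivalent_diameter"] = float(prop.equivalent_diameter_area)
    out["size.convex_area"] = float(prop.area_convex)
    out["size.major_axis"] = float(prop.axis_major_length)
    out["size.minor_axis"] = float(prop.axis_minor_length)

    # --- shape
    out["shape.factor"] = perim**2 / (4 * np.pi * area)  # inverse circularity
    minor = max(float(prop.axis_minor_length), 1e-9)
    out["shape.aspect_ratio"] = float(prop.axis_major_length) / minor
    out["shape.eccentricity"] = float(prop.eccentricity)
    out["shape.solidity"] = float(prop.solidity)
    out["shape.extent"] = float(prop.extent)

    # --- radius about centroid
    cy, cx = prop.centroid
    poly = _boundary_polygon(mask)
    radii = np.hypot(poly[:, 0] - cy, poly[:, 1] - cx)
    out["radius.mean"] = float(radii.mean())
    out["radius.sd"] = float(radii.std())
    out["radius.min"] = float(radii.min())
    out["radius.max"] = float(radii.max())
    out["radius.cv"] = float(radii.std() / max(radii.mean(), 1e-9))

    # --- curvature of the smoothed boundary
    sm = _smooth_closed(poly)
    k = _curvature(sm)
    out["curvature.mean"] = float(k.mean())
    out["curvature.sd"] = float(k.std())
    out["curvature.abs_mean"] = float(np.abs(k).mean())
    out["curvature.frac_positive"] = float((k > 0).mean())

    # --- central + scale-invariant moments
    mu = measure.moments_central(mask.astype(float))
    nu = measure.moments_normalized(mu)
    for (i, j) in ((0, 2), (2, 0), (1, 1), (0, 3), (3, 0), (2, 1), (1, 2)):
        out[f"moments.mu{i}{j}"] = float(mu[i, j])
        out[f"moments.nu{i}{j}"] = float(nu[i, j])
    hu = measure.moments_hu(nu)
    for i in range(4):
        out[f"moments.hu{i}"] = float(hu[i])

    # --- intensity (inside mask)
    vals = patch[mask]
    out["intensity.mean"] = float(vals.mean())
    out["intensity.sd"] = float(vals.std())
    out["intensity.median"] = float(np.median(vals))
    out["intensity.iqr"] = float(np.subtract(*np.percentile(vals, [75, 25])))
    out["intensity.skew"] = float(stats.skew(vals)) if vals.std() > 1e-12 else 0.0

    # --- co-occurrence texture on the quantized masked patch
    q = np.zeros_like(patch, dtype=np.uint8)
    vmin, vmax = vals.min(), vals.max()
    if vmax > vmin:
        q[mask] = 1 + np.minimum(
            ((patch[mask] - vmin) / (vmax - vmin) * 31).astype(np.uint8), 31
        )
    else:
        q[mask] = 1
    glcm = skfeature.graycomatrix(
        q, distances=[1], angles=[0, np.pi / 2], levels=33, symmetric=True, normed=False
    )
    glcm = glcm[1:, 1:, :, :].astype(np.float64)  # drop background level 0
    tot = glcm.sum(axis=(0, 1), keepdims=True)
    glcm = np.divide(glcm, tot, out=np.zeros_like(glcm), where=tot > 0)
    ii, jj = np.mgrid[0:32, 0:32]
    p = glcm.mean(axis=(2, 3))
    out["texture.contrast"] = float(((ii - jj) ** 2 * p).sum())
    out["texture.homogeneity"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(p), 0.0)
    out["texture.entropy"] = float(-(p * logp).sum())
    out["texture.energy"] = float((p**2).sum())

    # --- heterochromatin (bright) fraction by within-nucleus Otsu
    if vmax > vmin and len(np.unique(vals)) > 2:
        t = filters.threshold_otsu(vals)
        het = vals > t
        out["intensity.hetero_fraction"] = float(het.mean())
        eu_mean = vals[~het].mean() if (~het).any() else np.nan
        het_mean = vals[het].mean() if het.any() else np.nan
        out["intensity.hetero_eu_ratio"] = (
            float(het_mean / eu_mean) if eu_mean and np.isfinite(eu_mean) and eu_mean > 0 else 1.0
        )
    else:
        out["intensity.hetero_fraction"] = 0.0
        out["intensity.hetero_eu_ratio"] = 1.0
    return out


def feature_table(patches, masks, index=None) -> pd.DataFrame:
    """FeatureTable: one row per nucleus, one column per named feature."""
    rows = [compute_features(p, m) for p, m in zip(patches, masks)]
    df = pd.DataFrame(rows, index=index)
    return df


# ---------------------------------------------------------------------------
# Per-cluster discriminative testing


@dataclass
class FeatureStats:
    """Per (feature, cluster) Welch-test results with BH correction."""

    table: pd.DataFrame  # columns: feature, cluster, p, p_adj, fold_change,
    #                       mean_z, is_fold_change
    dropped: list[str]  # zero-variance features excluded

    def for_feature(self, name: str) -> pd.DataFrame:
        return self.table[self.table["feature"] == name]


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def test_cluster_features(table: pd.DataFrame, labels: np.ndarray) -> FeatureStats:
    """Welch t-test of each feature, in-cluster vs out-of-cluster, on z-scored
    values, BH-corrected jointly across all (feature, cluster) tests.

    Fold change uses the raw (pre-z-score) scale; features that are not
    strictly positive get a difference of means instead, flagged by
    ``is_fold_change``.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    dropped = [c for c in table.columns if table[c].std(ddof=0) <= 1e-12]
    if dropped:
        warnings.warn(f"excluding zero-variance features: {dropped}", stacklevel=2)
    feats = [c for c in table.columns if c not in dropped]
    z = (table[feats] - table[feats].mean()) / table[feats].std(ddof=0)

    rows = []
    for f in feats:
        raw = table[f].to_numpy(dtype=float)
        zv = z[f].to_numpy(dtype=float)
        positive = bool((raw > 0).all())
        for c in clusters:
            sel = labels == c
            if sel.sum() < 2 or (~sel).sum() < 2:
                continue
            t, p = stats.ttest_ind(zv[sel], zv[~sel], equal_var=False)
            if positive:
                fc = raw[sel].mean() / raw[~sel].mean()
            else:
                fc = raw[sel].mean() - raw[~sel].mean()
            rows.append(
                {
                    "feature": f,
                    "cluster": c,
                    "p": float(p),
                    "fold_change": float(fc),
                    "mean_z": float(zv[sel].mean()),
                    "is_fold_change": positive,
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    return FeatureStats(table=df, dropped=dropped)


def select_significant(
    stats_: FeatureStats,
    fdr: float = 0.01,
    fc_low: float = 0.8,
    fc_high: float = 1.2,
    z_min: float = 0.5,
    z_criterion: str = "mean_z",
) -> list[str]:
    """Features passing, in at least one cluster, ALL of: adjusted p < fdr,
    fold change outside [fc_low, fc_high], and |mean z in cluster| > z_min.

    ``z_criterion='raw_mean'`` switches the last gate to the alternative
    reading (cluster mean of the raw feature > z_min).
    """
    df = stats_.table
    sig = df["p_adj"] < fdr
    fc_gate = np.where(
        df["is_fold_change"],
        (df["fold_change"] > fc_high) | (df["fold_change"] < fc_low),
        np.abs(df["fold_change"]) > z_min,  # non-ratio features: effect-size gate
    )
    if z_criterion == "mean_z":
        z_gate = df["mean_z"].abs() > z_min
    elif z_criterion == "raw_mean":
        z_gate = df["mean_z"] > z_min
    else:
        raise ValueError("z_criterion must be 'mean_z' or 'raw_mean'")
    hit = df[sig & fc_gate & z_gate]
    return sorted(hit["feature"].unique().tolist())


def group_features(
    selected: list[str], table: pd.DataFrame, corr_threshold: float = 0.8
) -> dict[str, int]:
    """Group selected features by connected components of the |corr| > t graph
    on Pearson correlations. Components of size >= 2 are numbered 1..G by
    descending size; singletons go to the remainder group (G + 1).
    """
    if not selected:
        raise ValueError("no selected features to group")
    corr = table[selected].corr(method="pearson")
    n = len(selected)
    adj = corr.to_numpy() > corr_threshold
    np.fill_diagonal(adj, False)
    # union-find over the correlation graph
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    multi = sorted(
        (v for v in comps.values() if len(v) >= 2), key=lambda v: (-len(v), v[0])
    )
    groups: dict[str, int] = {}
    for gid, members in enumerate(multi, start=1):
        for i in members:
            groups[selected[i]] = gid
    remainder = len(multi) + 1
    for i in range(n):
        if selected[i] not in groups:
            groups[selected[i]] = remainder
    return groups
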