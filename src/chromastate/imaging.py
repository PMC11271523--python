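"""Image preprocessing, duct segmentation, stand-in nucleus segmentation,
and masked 96x96 patch extraction.

The nucleus segmenter here is a classical watershed stand-in for externally
trained deep segmenters; label masks produced elsewhere can be supplied to
:func:`extract_patches` directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

PATCH_SIZE = 96
PATCH_HALF = PATCH_SIZE // 2


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined on a (near-)constant image."""


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile range-normalization bounds (defaults: P1 and P99.8)."""

    low_percentile: float = 1.0
    high_percentile: float = 99.8

    def __post_init__(self):
        if not 0 <= self.low_percentile < self.high_percentile <= 100:
            raise ValueError("require 0 <= low < high <= 100")


@dataclass(frozen=True)
class AugmentationParams:
    """Random gain/offset and additive-noise augmentation parameters."""

    gain_range: tuple[float, float] = (0.6, 2.0)
    offset_range: tuple[float, float] = (-0.2, 0.2)
    noise_scale: float = 0.02

    def __post_init__(self):
        if self.gain_range[0] <= 0:
            raise ValueError("gain_range lower bound must be > 0")


@dataclass
class DuctMask:
    """Connected-component label image of duct regions (0 = background)."""

    labels: np.ndarray
    sample_id: str = ""

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class NucleusRecord:
    """One segmented nucleus with its patch-aligned mask and masked crop."""

    nucleus_id: int
    sample_id: str
    centroid: tuple[float, float]
    mask: np.ndarray
    patch: np.ndarray
    inside_duct: bool = False
    truncated: bool = False
    cluster: int | None = None
    subcluster: int | None = None
    meta: dict = field(default_factory=dict)


def range_normalize(image: np.ndarray, params: NormalizationParams | None = None) -> np.ndarray:
    """Percentile range-normalize: (I - P_low) / (P_high - P_low).

    Values outside [0, 1] are retained (no clipping); use ``np.clip`` for
    display. Percentiles use linear interpolation.
    """
    params = params or NormalizationParams()
    img = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(img, [params.low_percentile, params.high_percentile])
    if hi <= lo:
        raise DegenerateImageError(
            f"percentile range degenerate (P{params.low_percentile}={lo}, "
            f"P{params.high_percentile}={hi})"
        )
    return (img - lo) / (hi - lo)


def augment_intensity(
    image: np.ndarray,
    rng: np.random.Generator,
    params: AugmentationParams | None = None,
) -> np.ndarray:
    """Apply a random per-image affine intensity jitter I*a + b."""
    params = params or AugmentationParams()
    a = rng.uniform(*params.gain_range)
    b = rng.uniform(*params.offset_range)
    return np.asarray(image, dtype=np.float64) * a + b


def augment_noise(
    image: np.ndarray,
    rng: np.random.Generator,
    params: AugmentationParams | None = None,
) -> np.ndarray:
    """Add noise_scale * c * sigma with c ~ Unif(0,1) per image and
    sigma ~ Normal(0,1) per pixel."""
    params = params or AugmentationParams()
    img = np.asarray(image, dtype=np.float64)
    c = rng.uniform(0.0, 1.0)
    sigma = rng.standard_normal(img.shape)
    return img + params.noise_scale * c * sigma


def segment_ducts(
    cytokeratin_image: np.ndarray,
    min_area: int = 64,
    sigma: float = 1.0,
    sample_id: str = "",
) -> DuctMask:
    """Gaussian blur -> Otsu -> 8-connected components -> small-object removal."""
    img = np.asarray(cytokeratin_image, dtype=np.float64)
    if np.ptp(img) == 0:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    blurred = filters.gaussian(img, sigma=sigma, preserve_range=True)
    thresh = filters.threshold_otsu(blurred)
    binary = blurred > thresh
    if min_area > 0:
        binary = morphology.remove_small_objects(binary, max_size=min_area)
    labels = measure.label(binary, connectivity=2)
    return DuctMask(labels=labels.astype(np.int32), sample_id=sample_id)


def segment_nuclei(
    chromatin_image: np.ndarray,
    sigma: float = 1.5,
    min_distance: int = 7,
    min_area: int = 20,
    hole_area: int = 32,
    min_dynamic_range: float = 0.1,
) -> np.ndarray:
    """Stand-in nucleus segmenter: smooth -> Otsu -> distance-transform
    watershed -> small-hole removal. Returns a per-nucleus label image.

    Images whose dynamic range is below ``min_dynamic_range`` (relative to
    the [0, 1] normalized scale) are treated as empty: Otsu on pure noise
    would hallucinate objects. Intended for synthetic/clean images;
    externally produced label masks can be passed straight to
    :func:`extract_patches`.
    """
    img = np.asarray(chromatin_image, dtype=np.float64)
    if np.ptp(img) == 0:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    if np.ptp(img) < min_dynamic_range:
        return np.zeros(img.shape, dtype=np.int32)
    blurred = filters.gaussian(img, sigma=sigma, preserve_range=True)
    thresh = filters.threshold_otsu(blurred)
    binary = blurred > thresh
    binary = morphology.remove_small_objects(binary, max_size=min_area)
    binary = morphology.remove_small_holes(binary, max_size=hole_area)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    coords = feature.peak_local_max(
        distance, min_distance=min_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = segmentation.watershed(-distance, markers, mask=binary)
    # watershed can orphan markers; relabel contiguously
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


def label_centroids(labels: np.ndarray) -> list[tuple[float, float]]:
    """Centroids (row, col) of each positive label, in label order."""
    return [tuple(p.centroid) for p in measure.regionprops(labels)]


def extract_patches(
    image: np.ndarray,
    labels: np.ndarray,
    centroids: Sequence[tuple[float, float]] | None = None,
    duct_mask: DuctMask | None = None,
    sample_id: str = "",
) -> list[NucleusRecord]:
    """Crop a masked 96x96 patch around each nucleus centroid.

    Crops are zero-padded at image borders, multiplied by the nucleus's own
    binary mask (all pixels outside the mask are 0), and the centroid maps to
    patch pixel (48, 48). ``inside_duct`` is decided by centroid membership
    in any duct component.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != labels.shape:
        raise ValueError("image and label image must have the same shape")
    props = measure.regionprops(labels)
    if centroids is None:
        centroids = [p.centroid for p in props]
    if len(centroids) != len(props):
        raise ValueError("centroid count does not match label count")

    h, w = image.shape
    records = []
    for prop, centroid in zip(props, centroids):
        r0 = int(round(centroid[0])) - PATCH_HALF
        c0 = int(round(centroid[1])) - PATCH_HALF
        patch = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=np.float64)
        mask = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=bool)
        rlo, rhi = max(r0, 0), min(r0 + PATCH_SIZE, h)
        clo, chi = max(c0, 0), min(c0 + PATCH_SIZE, w)
        if rlo < rhi and clo < chi:
            sub_img = image[rlo:rhi, clo:chi]
            sub_lab = labels[rlo:rhi, clo:chi] == prop.label
            pr, pc = rlo - r0, clo - c0
            mask[pr : pr + sub_lab.shape[0], pc : pc + sub_lab.shape[1]] = sub_lab
            patch[pr : pr + sub_lab.shape[0], pc : pc + sub_lab.shape[1]] = (
                sub_img * sub_lab
            )
        truncated = False
        bb = prop.bbox
        if bb[2] - bb[0] > PATCH_SIZE or bb[3] - bb[1] > PATCH_SIZE:
            truncated = True
            warnings.warn(
                f"nucleus {prop.label} larger than {PATCH_SIZE}x{PATCH_SIZE} patch; truncated",
                stacklevel=2,
            )
        inside = False
        if duct_mask is not None:
            rr = min(max(int(round(centroid[0])), 0), h - 1)
            cc = min(max(int(round(centroid[1])), 0), w - 1)
            inside = bool(duct_mask.labels[rr, cc] > 0)
        records.append(
            NucleusRecord(
                nucleus_id=int(prop.label),
                sample_id=sample_id,
                centroid=(float(centroid[0]), float(centroid[1])),
                mask=mask,
                patch=patch,
                inside_duct=inside,
                truncated=truncated,
            )
        )
    return records
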