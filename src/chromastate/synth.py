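"""Seeded synthetic tissue-core generator.

Produces cohorts of patients and samples with planted single-nucleus states,
duct masks, and rendered chromatin / cytokeratin channels, so that the full
downstream pipeline (segmentation -> representation -> clustering -> spatial
statistics -> classification) can be exercised and validated against known
ground truth without any external data.

Planted structure:

* 8 cell states present in every phenotypic category, at category-dependent
  proportions (low-index states enriched in non-tumor categories, high-index
  states in DCIS/IDC categories);
* state-dependent nuclear morphology — mean area increases with state index
  while aspect ratio and chromatin heterogeneity vary orthogonally;
* tunable same-state spatial assortativity and per-state duct affinity;
* a hard-core non-overlap constraint so rendered masks never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import filters

from .imaging import PATCH_HALF, PATCH_SIZE

N_STATES = 8

#: phenotypic category codes and their disease stages
STAGES = ("non-tumor", "DCIS", "IDC")
CATEGORY_STAGE = {
    "P0": "non-tumor",   # breast tissue
    "P1": "non-tumor",   # cancer adjacent breast tissue
    "P2": "non-tumor",   # non-tumoral tissue adjacent to IDC
    "P3": "non-tumor",   # hyperplasia
    "P4": "non-tumor",   # atypical hyperplasia
    "P5": "DCIS",
    "P6": "DCIS",        # DCIS and breast tissue
    "P7": "DCIS",        # DCIS with early infiltration
    "P8": "DCIS",        # micropapillary DCIS with early infiltration
    "P9": "IDC",         # IDC and breast tissue
    "P10": "IDC",
}
ALL_CATEGORIES = tuple(CATEGORY_STAGE)


class ConfigurationError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class StateMorphology:
    """Per-state nucleus rendering parameters (areas in px^2)."""

    mean_area_px2: float
    aspect_ratio: float = 1.0
    roughness: float = 0.05
    heterogeneity: float = 0.2
    area_cv: float = 0.06

    def __post_init__(self):
        if min(self.mean_area_px2, self.aspect_ratio) <= 0:
            raise ParameterError("area and aspect ratio must be positive")
        if self.roughness < 0 or self.heterogeneity < 0:
            raise ParameterError("roughness and heterogeneity must be >= 0")


def default_morphologies() -> tuple[StateMorphology, ...]:
    """Mean area strictly increasing (geometrically) with state index, plus a
    single orthogonal axis on which circular-but-heterogeneous nuclei trade
    off against elongated-but-homogeneous ones (circularity and chromatin
    homogeneity co-vary, orthogonally to the size trend)."""
    out = []
    for s in range(N_STATES):
        circular = s % 2 == 0
        out.append(
            StateMorphology(
                mean_area_px2=80.0 * 1.25**s,
                aspect_ratio=1.0 if circular else 2.0,
                roughness=0.04 if s < 4 else 0.12,
                heterogeneity=0.65 if circular else 0.08,
                area_cv=0.05,
            )
        )
    return tuple(out)


def stage_of(category: str) -> str:
    return CATEGORY_STAGE[category]


def default_state_proportions(categories) -> np.ndarray:
    """Category x state proportions: states 0-2 enriched in non-tumor,
    5-7 in DCIS/IDC, all entries strictly positive."""
    centers = {"non-tumor": 1.2, "DCIS": 4.2, "IDC": 6.2}
    widths = {"non-tumor": 1.6, "DCIS": 1.9, "IDC": 1.6}
    states = np.arange(N_STATES)
    rows = []
    for cat in categories:
        stage = stage_of(cat)
        # spread category centers a little within a stage for heterogeneity
        offset = 0.25 * (int(cat[1:]) % 3 - 1)
        w = np.exp(-0.5 * ((states - centers[stage] - offset) / widths[stage]) ** 2)
        w += 0.02  # every state present in every category
        rows.append(w / w.sum())
    return np.asarray(rows)


@dataclass
class CohortConfig:
    n_patients: int = 6
    samples_per_patient: int = 2
    categories: tuple[str, ...] = ("P0", "P1", "P3", "P5", "P7", "P9", "P10")
    pixel_size_um: float = 0.18
    image_size_px: int = 500
    cells_per_sample: int = 100
    state_proportions: np.ndarray | None = None
    assortativity: float = 0.0
    duct_affinity: np.ndarray | None = None
    morphology_params: tuple[StateMorphology, ...] = field(
        default_factory=default_morphologies
    )
    patient_effect: float = 0.0  # Dirichlet concentration; 0 disables
    interaction_radius_px: float = 40.0
    duct_scale_px: float = 80.0
    duct_fraction: float = 0.12
    noise_sd: float = 0.02
    bg_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.state_proportions is None:
            self.state_proportions = default_state_proportions(self.categories)
        self.state_proportions = np.asarray(self.state_proportions, dtype=float)
        if self.duct_affinity is None:
            self.duct_affinity = np.zeros(N_STATES)
        self.duct_affinity = np.asarray(self.duct_affinity, dtype=float)
        self.validate()

    def validate(self) -> None:
        unknown = set(self.categories) - set(ALL_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        sp = self.state_proportions
        if sp.shape != (len(self.categories), N_STATES):
            raise ConfigurationError(
                f"state_proportions must be {len(self.categories)}x{N_STATES}, got {sp.shape}"
            )
        if not np.allclose(sp.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigurationError("each state_proportions row must sum to 1")
        if (sp <= 0).any():
            raise ConfigurationError("all state proportions must be > 0")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.cells_per_sample < N_STATES:
            raise ConfigurationError(f"cells_per_sample must be >= {N_STATES}")
        if self.duct_affinity.shape != (N_STATES,):
            raise ConfigurationError("duct_affinity must be an 8-vector")
        if self.assortativity < 0:
            raise ConfigurationError("assortativity must be >= 0")
        if self.n_patients * self.samples_per_patient < len(self.categories):
            raise ConfigurationError("not enough samples to cover all categories")


@dataclass
class NucleusTruth:
    nucleus_id: int
    centroid: tuple[float, float]  # (row, col) px
    state: int
    mask: np.ndarray  # 96x96 patch-aligned
    patch: np.ndarray  # 96x96 rendered intensities
    max_radius: float


@dataclass
class SyntheticSample:
    sample_id: str
    patient_id: str
    core_id: str
    category: str
    stage: str
    chromatin_image: np.ndarray
    cytokeratin_image: np.ndarray
    duct_mask_truth: np.ndarray
    nuclei_truth: list[NucleusTruth]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([n.centroid for n in self.nuclei_truth], dtype=float)

    @property
    def states(self) -> np.ndarray:
        return np.array([n.state for n in self.nuclei_truth], dtype=int)


# ---------------------------------------------------------------------------
# Nucleus rendering


def render_nucleus(
    state: int,
    morphology_params,
    rng: np.random.Generator,
    patch_size: int = PATCH_SIZE,
):
    """Render one nucleus: roughened ellipse mask + blob-textured interior.

    Returns ``(mask, patch)`` with the patch zero outside the mask and the
    shape centered at the patch center.
    """
    if isinstance(morphology_params, (tuple, list)):
        params = morphology_params[state]
    else:
        params = morphology_params
    area = params.mean_area_px2
    if params.area_cv > 0:
        area *= float(np.exp(rng.normal(0.0, params.area_cv)))
    q = params.aspect_ratio
    a = np.sqrt(area * q / np.pi)  # major semi-axis
    b = np.sqrt(area / (np.pi * q))
    limit = patch_size / 2 - 2
    if a * (1 + 3 * params.roughness) >= limit:
        raise ParameterError(
            f"nucleus area {area:.0f} px^2 (aspect {q}) too large for "
            f"{patch_size}x{patch_size} patch"
        )
    theta = rng.uniform(0, np.pi)
    phi = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    r_ell = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    if params.roughness > 0:
        pert = np.zeros_like(phi)
        for h in (2, 3, 5, 7):
            pert += rng.normal() * np.cos(h * phi) + rng.normal() * np.sin(h * phi)
        pert /= max(pert.std(), 1e-9)
        r_ell = r_ell * np.clip(1 + params.roughness * pert, 0.3, None)
    c = patch_size / 2
    rows = c + r_ell * np.sin(phi + theta)
    cols = c + r_ell * np.cos(phi + theta)
    rr, cc = skdraw.polygon(rows, cols, shape=(patch_size, patch_size))
    mask = np.zeros((patch_size, patch_size), dtype=bool)
    mask[rr, cc] = True
    mask = ndi.binary_fill_holes(mask)

    # interior texture: heterogeneity brightens the nucleus, adds a bright
    # perinuclear rim (condensed-chromatin band), and seeds mild blob noise
    het = params.heterogeneity
    base = 0.42 + 0.45 * min(het, 1.0)
    tex = np.full((patch_size, patch_size), base)
    if het > 0 and mask.any():
        dist_in = ndi.distance_transform_edt(mask)
        rel = dist_in / max(dist_in.max(), 1e-9)  # 1 at center, 0 at rim
        rim = np.exp(-(((rel - 0.25) / 0.2) ** 2))
        field_ = filters.gaussian(
            rng.standard_normal((patch_size, patch_size)), sigma=2.5, preserve_range=True
        )
        field_ /= max(field_.std(), 1e-9)
        tex = tex + het * (0.45 * rim - 0.18) + 0.22 * het * field_
    patch = np.clip(tex, 0.08, 1.0) * mask
    return mask, patch


# ---------------------------------------------------------------------------
# Duct masks and cell placement


def make_duct_mask(
    rng: np.random.Generator, size: int, duct_fraction: float = 0.12, n_ducts: int = 2
) -> np.ndarray:
    """A few elliptical duct regions covering roughly ``duct_fraction`` of area."""
    mask = np.zeros((size, size), dtype=bool)
    if duct_fraction <= 0 or n_ducts <= 0:
        return mask
    radius = np.sqrt(duct_fraction * size * size / (np.pi * n_ducts))
    for _ in range(n_ducts):
        r0 = rng.uniform(0.25 * size, 0.75 * size)
        c0 = rng.uniform(0.25 * size, 0.75 * size)
        rr, cc = skdraw.ellipse(
            r0,
            c0,
            radius * rng.uniform(0.8, 1.2),
            radius * rng.uniform(0.8, 1.2),
            shape=(size, size),
            rotation=rng.uniform(0, np.pi),
        )
        mask[rr, cc] = True
    return mask


def _place_cells(
    states: np.ndarray,
    radii: np.ndarray,
    config: CohortConfig,
    duct_dist: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int = 40,
    max_rounds: int = 120,
) -> np.ndarray:
    """Sequential soft-core placement.

    Each cell picks among uniform candidate positions with probability
    proportional to ``exp(duct_term + assortativity * n_same_nearby)``,
    subject to a hard-core non-overlap constraint on rendered radii.
    Callers should place large nuclei first to avoid jamming.
    """
    size = config.image_size_px
    margin = 20.0
    placed = np.full((len(states), 2), np.nan)
    placed_r = np.zeros(len(states))
    d_scale = config.duct_scale_px
    for i, s in enumerate(states):
        chosen = None
        for _ in range(max_rounds):
            cand = rng.uniform(margin, size - margin, size=(n_candidates, 2))
            if i > 0:
                prev = placed[:i]
                dist = np.hypot(
                    cand[:, None, 0] - prev[None, :, 0],
                    cand[:, None, 1] - prev[None, :, 1],
                )
                min_sep = placed_r[:i][None, :] + radii[i] + 2.0
                ok = (dist > min_sep).all(axis=1)
            else:
                ok = np.ones(n_candidates, dtype=bool)
            if not ok.any():
                continue
            cand = cand[ok]
            logw = np.zeros(len(cand))
            if config.duct_affinity[s] != 0:
                dd = duct_dist[
                    cand[:, 0].astype(int), cand[:, 1].astype(int)
                ]
                logw += config.duct_affinity[s] * (1.0 - np.minimum(dd, d_scale) / d_scale)
            if config.assortativity > 0 and i > 0:
                same = placed[:i][states[:i] == s]
                if len(same):
                    dist_same = np.hypot(
                        cand[:, None, 0] - same[None, :, 0],
                        cand[:, None, 1] - same[None, :, 1],
                    )
                    n_near = (dist_same < config.interaction_radius_px).sum(axis=1)
                    logw += config.assortativity * np.minimum(n_near, 6)
            w = np.exp(logw - logw.max())
            chosen = cand[rng.choice(len(cand), p=w / w.sum())]
            break
        if chosen is None:
            raise ConfigurationError(
                "could not place all cells; reduce cells_per_sample or nucleus areas"
            )
        placed[i] = chosen
        placed_r[i] = radii[i]
    return placed


# ---------------------------------------------------------------------------
# Tissue rendering


def render_tissue(
    nuclei: list[NucleusTruth],
    duct_mask: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float = 0.02,
    bg_level: float = 0.05,
):
    """Compose chromatin and cytokeratin channels from placed nuclei.

    With ``noise_sd = 0`` and ``bg_level = 0`` the chromatin channel is
    exactly the sum of the placed patches.
    """
    size = duct_mask.shape[0]
    chromatin = np.zeros((size, size), dtype=np.float64)
    for nuc in nuclei:
        r0 = int(round(nuc.centroid[0])) - PATCH_HALF
        c0 = int(round(nuc.centroid[1])) - PATCH_HALF
        rlo, rhi = max(r0, 0), min(r0 + PATCH_SIZE, size)
        clo, chi = max(c0, 0), min(c0 + PATCH_SIZE, size)
        chromatin[rlo:rhi, clo:chi] += nuc.patch[
            rlo - r0 : rhi - r0, clo - c0 : chi - c0
        ]
    if bg_level or noise_sd:
        bg = bg_level + noise_sd * rng.standard_normal((size, size))
        chromatin = np.clip(chromatin + bg, 0.0, 1.0)

    cyto = np.where(duct_mask, 0.75, 0.12).astype(np.float64)
    cyto = filters.gaussian(cyto, sigma=3.0, preserve_range=True)
    if noise_sd:
        cyto = cyto + 2.0 * noise_sd * rng.standard_normal((size, size))
    cyto = np.clip(cyto, 0.0, 1.0)
    return chromatin, cyto


# ---------------------------------------------------------------------------
# Cohort generation


def _sample_categories(config: CohortConfig) -> list[str]:
    """Round-robin category assignment over (patient, sample) slots so every
    requested category appears at least once."""
    n_slots = config.n_patients * config.samples_per_patient
    cats = list(config.categories)
    return [cats[i % len(cats)] for i in range(n_slots)]


def generate_sample(
    config: CohortConfig,
    category: str,
    proportions: np.ndarray,
    sample_id: str,
    patient_id: str,
    core_id: str,
    rng: np.random.Generator,
) -> SyntheticSample:
    counts = rng.multinomial(config.cells_per_sample, proportions)
    states = np.repeat(np.arange(N_STATES), counts)
    rng.shuffle(states)

    duct_mask = make_duct_mask(rng, config.image_size_px, config.duct_fraction)
    duct_dist = ndi.distance_transform_edt(~duct_mask)

    rendered = [render_nucleus(s, config.morphology_params, rng) for s in states]
    radii = np.array(
        [
            np.max(
                np.hypot(*(np.argwhere(mask) - np.array([PATCH_HALF, PATCH_HALF])).T)
            )
            if mask.any()
            else 1.0
            for mask, _ in rendered
        ]
    )
    # place large nuclei first: packing is much easier and stays seeded
    order = np.argsort(-radii, kind="stable")
    states = states[order]
    rendered = [rendered[i] for i in order]
    radii = radii[order]
    positions = _place_cells(states, radii, config, duct_dist, rng)

    nuclei = [
        NucleusTruth(
            nucleus_id=i,
            centroid=(float(positions[i, 0]), float(positions[i, 1])),
            state=int(states[i]),
            mask=rendered[i][0],
            patch=rendered[i][1],
            max_radius=float(radii[i]),
        )
        for i in range(len(states))
    ]
    chromatin, cyto = render_tissue(
        nuclei, duct_mask, rng, noise_sd=config.noise_sd, bg_level=config.bg_level
    )
    return SyntheticSample(
        sample_id=sample_id,
        patient_id=patient_id,
        core_id=core_id,
        category=category,
        stage=stage_of(category),
        chromatin_image=chromatin,
        cytokeratin_image=cyto,
        duct_mask_truth=duct_mask,
        nuclei_truth=nuclei,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticSample]:
    """Generate a full synthetic cohort, deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cat_index = {c: i for i, c in enumerate(config.categories)}
    slot_categories = _sample_categories(config)
    samples = []
    slot = 0
    for p in range(config.n_patients):
        patient_id = f"patient{p:03d}"
        # optional patient-level random effect on state proportions
        patient_props = {}
        for cat in config.categories:
            base = config.state_proportions[cat_index[cat]]
            if config.patient_effect > 0:
                patient_props[cat] = rng.dirichlet(base * config.patient_effect)
            else:
                patient_props[cat] = base
        for k in range(config.samples_per_patient):
            cat = slot_categories[slot]
            sample_id = f"sample{slot:03d}"
            core_id = f"core{p:03d}_{k}"
            samples.append(
                generate_sample(
                    config,
                    cat,
                    patient_props[cat],
                    sample_id,
                    patient_id,
                    core_id,
                    rng,
                )
            )
            slot += 1
    return samples


def cohort_metadata(samples: list[SyntheticSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "patient_id": [s.patient_id for s in samples],
            "core_id": [s.core_id for s in samples],
            "category": [s.category for s in samples],
            "stage": [s.stage for s in samples],
            "n_cells": [len(s.nuclei_truth) for s in samples],
        }
    )


def truth_table(samples: list[SyntheticSample]) -> pd.DataFrame:
    """Long-format ground-truth table (one row per nucleus)."""
    rows = []
    for s in samples:
        for nuc in s.nuclei_truth:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "patient_id": s.patient_id,
                    "category": s.category,
                    "stage": s.stage,
                    "nucleus_id": nuc.nucleus_id,
                    "row": nuc.centroid[0],
                    "col": nuc.centroid[1],
                    "state": nuc.state,
                }
            )
    return pd.DataFrame(rows)


def match_centroids(
    pred: np.ndarray, truth: np.ndarray, max_dist: float = 5.0
) -> list[tuple[int, int]]:
    """Greedy nearest match of predicted to true centroids within ``max_dist``.

    Returns (pred_index, truth_index) pairs; each truth centroid is used once.
    Used by parameter-recovery tests to compare planted and recovered labels.
    """
    from scipy.spatial import cKDTree

    if len(pred) == 0 or len(truth) == 0:
        return []
    tree = cKDTree(truth)
    dist, idx = tree.query(pred)
    order = np.argsort(dist)
    used, pairs = set(), []
    for i in order:
        if dist[i] > max_dist:
            break
        j = int(idx[i])
        if j in used:
            continue
        used.add(j)
        pairs.append((int(i), j))
    return pairs


def write_cohort(samples: list[SyntheticSample], outdir) -> None:
    """Write per-sample TIFFs (16-bit), duct-mask TIFFs, PNG quick-looks,
    and the ground-truth / metadata CSVs."""
    import imageio.v3 as iio
    import tifffile
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        chrom16 = (np.clip(s.chromatin_image, 0, 1) * 65535).astype(np.uint16)
        cyto16 = (np.clip(s.cytokeratin_image, 0, 1) * 65535).astype(np.uint16)
        tifffile.imwrite(out / f"{s.sample_id}_chromatin.tif", chrom16)
        tifffile.imwrite(out / f"{s.sample_id}_cytokeratin.tif", cyto16)
        tifffile.imwrite(
            out / f"{s.sample_id}_duct_truth.tif",
            s.duct_mask_truth.astype(np.uint8) * 255,
        )
        iio.imwrite(
            out / f"{s.sample_id}_quicklook.png",
            (np.clip(s.chromatin_image, 0, 1) * 255).astype(np.uint8),
        )
    truth_table(samples).to_csv(out / "ground_truth.csv", index=False)
    cohort_metadata(samples).to_csv(out / "metadata.csv", index=False)
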