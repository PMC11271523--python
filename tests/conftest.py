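"""Shared fixtures: small synthetic cohorts and derived artifacts.

Session-scoped fixtures keep the expensive generator and round-trip pipeline
runs to one apiece.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromastate import imaging, synth


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Tiny cohort: 2 patients x 2 samples, 3 categories, fast to generate."""
    return synth.CohortConfig(
        n_patients=2,
        samples_per_patient=2,
        categories=("P0", "P5", "P10"),
        image_size_px=300,
        cells_per_sample=40,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synth.generate_cohort(small_config)


@pytest.fixture(scope="session")
def one_sample(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def segmented_sample(one_sample):
    """(sample, normalized image, nucleus labels, records) round trip."""
    img = imaging.range_normalize(one_sample.chromatin_image)
    labels = imaging.segment_nuclei(img)
    duct = imaging.segment_ducts(one_sample.cytokeratin_image)
    records = imaging.extract_patches(
        img, labels, duct_mask=duct, sample_id=one_sample.sample_id
    )
    return one_sample, img, labels, records


def make_disk_patch(radius: int, size: int = 96, value: float = 0.7):
    """Analytic disk mask+patch used for closed-form morphometry tests."""
    rr, cc = np.mgrid[0:size, 0:size]
    c = size // 2
    mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    return mask, mask * value


def make_ellipse_patch(a: float, b: float, size: int = 96, value: float = 0.7):
    rr, cc = np.mgrid[0:size, 0:size]
    c = size // 2
    mask = ((rr - c) / b) ** 2 + ((cc - c) / a) ** 2 <= 1.0
    return mask, mask * value
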