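"""Generator tests: determinism, planted proportions, morphology recovery,
rendering contracts, and the exchangeable-null fold-change property."""

import numpy as np
import pytest
from scipy import stats as sstats

from chromastate import imaging, spatial, synth


def _flat_morphologies():
    # identical morphology for all states: labels are exactly exchangeable
    return tuple(
        synth.StateMorphology(mean_area_px2=80.0, aspect_ratio=1.0, roughness=0.0,
                              heterogeneity=0.0, area_cv=0.0)
        for _ in range(synth.N_STATES)
    )


class TestConfigValidation:
    def test_row_not_summing_raises(self):
        sp = synth.default_state_proportions(("P0", "P5"))
        sp[0] = sp[0] * 0.5
        with pytest.raises(synth.ConfigurationError):
            synth.CohortConfig(
                n_patients=2, samples_per_patient=1, categories=("P0", "P5"),
                state_proportions=sp,
            )

    def test_zero_proportion_raises(self):
        sp = synth.default_state_proportions(("P0", "P5"))
        sp[0, 3] = 0.0
        sp[0] /= sp[0].sum()
        with pytest.raises(synth.ConfigurationError):
            synth.CohortConfig(
                n_patients=2, samples_per_patient=1, categories=("P0", "P5"),
                state_proportions=sp,
            )

    def test_too_few_cells_raises(self):
        with pytest.raises(synth.ConfigurationError):
            synth.CohortConfig(cells_per_sample=4)

    def test_default_rows_are_simplex(self):
        cfg = synth.CohortConfig()
        np.testing.assert_allclose(cfg.state_proportions.sum(axis=1), 1.0)
        assert (cfg.state_proportions > 0).all()


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config):
        a = synth.generate_cohort(small_config)
        b = synth.generate_cohort(small_config)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.chromatin_image, sb.chromatin_image)
            np.testing.assert_array_equal(sa.cytokeratin_image, sb.cytokeratin_image)
            np.testing.assert_array_equal(sa.duct_mask_truth, sb.duct_mask_truth)
            assert sa.states.tolist() == sb.states.tolist()
            np.testing.assert_array_equal(sa.centroids, sb.centroids)

    def test_different_seed_differs(self, small_config, small_cohort):
        import dataclasses

        cfg2 = dataclasses.replace(small_config, seed=small_config.seed + 1)
        other = synth.generate_cohort(cfg2)
        assert not np.array_equal(
            other[0].chromatin_image, small_cohort[0].chromatin_image
        )


class TestCohortStructure:
    def test_every_category_appears(self, small_cohort, small_config):
        assert {s.category for s in small_cohort} == set(small_config.categories)

    def test_all_states_in_every_category_at_scale(self):
        cfg = synth.CohortConfig(
            n_patients=2, samples_per_patient=2, categories=("P0", "P10"),
            cells_per_sample=400, image_size_px=950, seed=3,
        )
        samples = synth.generate_cohort(cfg)
        for cat in cfg.categories:
            states = np.concatenate(
                [s.states for s in samples if s.category == cat]
            )
            assert set(states.tolist()) == set(range(synth.N_STATES))

    def test_state_fractions_match_planted_proportions(self):
        # binomial CI check on a reference proportion row
        row = np.array([0.3, 0.25, 0.2, 0.1, 0.06, 0.04, 0.03, 0.02])
        sp = np.tile(row, (1, 1))
        n = 600
        cfg = synth.CohortConfig(
            n_patients=2, samples_per_patient=1, categories=("P0",),
            state_proportions=sp, cells_per_sample=n, image_size_px=900, seed=5,
        )
        samples = synth.generate_cohort(cfg)
        counts = np.zeros(synth.N_STATES)
        for s in samples:
            counts += np.bincount(s.states, minlength=synth.N_STATES)
        total = counts.sum()
        for k in range(synth.N_STATES):
            se = np.sqrt(row[k] * (1 - row[k]) / total)
            assert abs(counts[k] / total - row[k]) < 4 * se + 1e-9

    def test_centroids_inside_bounds_and_no_mask_overlap(self, small_cohort):
        for s in small_cohort:
            size = s.chromatin_image.shape[0]
            assert (s.centroids >= 0).all() and (s.centroids < size).all()
            # paste all masks into one canvas; overlap would exceed 1 anywhere
            canvas = np.zeros((size, size))
            for nuc in s.nuclei_truth:
                r0 = int(round(nuc.centroid[0])) - 48
                c0 = int(round(nuc.centroid[1])) - 48
                rlo, rhi = max(r0, 0), min(r0 + 96, size)
                clo, chi = max(c0, 0), min(c0 + 96, size)
                canvas[rlo:rhi, clo:chi] += nuc.mask[
                    rlo - r0 : rhi - r0, clo - c0 : chi - c0
                ]
            assert canvas.max() <= 1.0


class TestRenderNucleus:
    def test_zero_roughness_unit_aspect_is_disk(self, rng):
        params = synth.StateMorphology(
            mean_area_px2=400.0, aspect_ratio=1.0, roughness=0.0,
            heterogeneity=0.0, area_cv=0.0,
        )
        mask, patch = synth.render_nucleus(0, params, rng)
        from skimage import measure

        prop = measure.regionprops(mask.astype(np.uint8))[0]
        shape_factor = prop.perimeter**2 / (4 * np.pi * prop.area)
        assert abs(shape_factor - 1.0) < 0.05
        assert patch[~mask].sum() == 0

    def test_aspect_ratio_two(self, rng):
        params = synth.StateMorphology(
            mean_area_px2=400.0, aspect_ratio=2.0, roughness=0.0,
            heterogeneity=0.0, area_cv=0.0,
        )
        mask, _ = synth.render_nucleus(0, params, rng)
        from skimage import measure

        prop = measure.regionprops(mask.astype(np.uint8))[0]
        ratio = prop.axis_major_length / prop.axis_minor_length
        assert abs(ratio - 2.0) / 2.0 < 0.10

    def test_mean_areas_strictly_increasing_over_states(self, rng):
        morphs = synth.default_morphologies()
        means = []
        for s in range(synth.N_STATES):
            areas = [
                synth.render_nucleus(s, morphs, rng)[0].sum() for _ in range(15)
            ]
            means.append(np.mean(areas))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_oversized_area_raises(self, rng):
        params = synth.StateMorphology(mean_area_px2=9000.0, aspect_ratio=2.0)
        with pytest.raises(synth.ParameterError):
            synth.render_nucleus(0, params, rng)


class TestRenderTissue:
    def test_zero_nuclei_pure_background(self, rng):
        duct = np.zeros((120, 120), dtype=bool)
        chrom, _ = synth.render_tissue([], duct, rng, noise_sd=0.02, bg_level=0.05)
        assert chrom.shape == (120, 120)
        assert abs(chrom.mean() - 0.05) < 0.01

    def test_zero_noise_equals_sum_of_patches(self, small_config, rng):
        cfg = small_config
        props = cfg.state_proportions[0]
        r = np.random.default_rng(0)
        sample = synth.generate_sample(
            cfg, "P0", props, "s", "p", "c", r
        )
        chrom, _ = synth.render_tissue(
            sample.nuclei_truth, sample.duct_mask_truth,
            np.random.default_rng(1), noise_sd=0.0, bg_level=0.0,
        )
        expected = np.zeros_like(chrom)
        for nuc in sample.nuclei_truth:
            r0 = int(round(nuc.centroid[0])) - 48
            c0 = int(round(nuc.centroid[1])) - 48
            rlo, rhi = max(r0, 0), min(r0 + 96, chrom.shape[0])
            clo, chi = max(c0, 0), min(c0 + 96, chrom.shape[1])
            expected[rlo:rhi, clo:chi] += nuc.patch[
                rlo - r0 : rhi - r0, clo - c0 : chi - c0
            ]
        np.testing.assert_array_equal(chrom, expected)

    def test_duct_recovered_by_otsu_segmentation(self, one_sample):
        duct = imaging.segment_ducts(one_sample.cytokeratin_image)
        pred = duct.binary
        truth = one_sample.duct_mask_truth
        inter = (pred & truth).sum()
        union = (pred | truth).sum()
        assert inter / union > 0.8


class TestExchangeableNull:
    def test_fold_change_near_one_when_assortativity_zero(self):
        cfg = synth.CohortConfig(
            n_patients=1, samples_per_patient=1, categories=("P0",),
            state_proportions=np.full((1, 8), 1 / 8), cells_per_sample=300,
            image_size_px=500, assortativity=0.0,
            duct_affinity=np.full(8, 0.5),  # uniform: still exchangeable
            morphology_params=_flat_morphologies(), seed=11,
        )
        s = synth.generate_cohort(cfg)[0]
        null = spatial.permutation_null(
            s.centroids, s.states, n_shuffles=500, seed=0, radius_um=20.0
        )
        fc = null.fold_change
        assert np.nanmax(np.abs(fc - 1.0)) < 0.40
        # mean absolute deviation small
        assert np.nanmean(np.abs(fc - 1.0)) < 0.10

    def test_assortative_cohort_has_enriched_diagonal(self):
        cfg = synth.CohortConfig(
            n_patients=1, samples_per_patient=1, categories=("P0",),
            state_proportions=np.full((1, 8), 1 / 8), cells_per_sample=150,
            image_size_px=500, assortativity=1.2,
            morphology_params=_flat_morphologies(), seed=13,
        )
        s = synth.generate_cohort(cfg)[0]
        null = spatial.permutation_null(
            s.centroids, s.states, n_shuffles=300, seed=0, radius_um=8.0
        )
        diag = np.diag(null.fold_change)
        assert np.nanmean(diag) > 1.1


class TestWriters:
    def test_write_cohort_outputs(self, tmp_path, small_cohort):
        synth.write_cohort(small_cohort[:1], tmp_path)
        sid = small_cohort[0].sample_id
        for suffix in ("chromatin.tif", "cytokeratin.tif", "duct_truth.tif",
                       "quicklook.png"):
            assert (tmp_path / f"{sid}_{suffix}").exists()
        import pandas as pd

        truth = pd.read_csv(tmp_path / "ground_truth.csv")
        assert {"nucleus_id", "row", "col", "state", "sample_id"} <= set(truth.columns)

    def test_truth_table_states_in_range(self, small_cohort):
        df = synth.truth_table(small_cohort)
        assert df["state"].between(0, 7).all()

    def test_patient_effect_perturbs_proportions(self):
        cfg = synth.CohortConfig(
            n_patients=2, samples_per_patient=1, categories=("P0",),
            cells_per_sample=200, image_size_px=600,
            patient_effect=20.0, seed=9,
        )
        samples = synth.generate_cohort(cfg)
        f0 = np.bincount(samples[0].states, minlength=8) / len(samples[0].states)
        f1 = np.bincount(samples[1].states, minlength=8) / len(samples[1].states)
        assert not np.allclose(f0, f1, atol=0.01)
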