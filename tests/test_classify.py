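"""Classifier tests: MLP mechanics, LOPO CV leakage and accuracy, ablation,
misclassification contrasts, subsetting, and the logistic baseline."""

import numpy as np
import pandas as pd
import pytest

from chromastate import classify, spatial
from chromastate.classify import (
    CategoryGrouping,
    MLPSpec,
    SampleSpatial,
    default_grouping,
)

FAST = MLPSpec(hidden_sizes=(32, 32, 32), epochs=120, patience=20, seed=0)


def _signal_cohort(rng, n_patients=8, samples_per_patient=2, noise=0.05):
    """Sample-level features where category determines the mean; patients
    nested in categories arbitrarily."""
    cats = ["P0", "P3", "P5", "P10"]
    means = {c: rng.uniform(-2, 2, size=10) for c in cats}
    X, y, pids, sids = [], [], [], []
    k = 0
    for p in range(n_patients):
        for s in range(samples_per_patient):
            c = cats[k % len(cats)]
            X.append(means[c] + noise * rng.standard_normal(10))
            y.append(c)
            pids.append(f"pat{p}")
            sids.append(f"s{k}")
            k += 1
    return np.array(X), np.array(y), np.array(pids), np.array(sids)


class TestMLP:
    def test_separable_two_class_zero_error(self, rng):
        X = np.concatenate([rng.normal(-5, 0.3, (40, 4)), rng.normal(5, 0.3, (40, 4))])
        y = np.array(["a"] * 40 + ["b"] * 40)
        _, conf = classify.train_mlp(X, y, FAST)
        off_diag = conf.to_numpy().sum() - np.trace(conf.to_numpy())
        assert off_diag == 0

    def test_inverse_frequency_weights(self):
        y = np.array(["a"] * 10 + ["b"] * 40)
        w = classify.inverse_frequency_weights(y)
        assert w["a"] / w["b"] == pytest.approx(4.0)

    def test_absent_class_raises(self):
        X = np.zeros((4, 3))
        model = classify.MLPClassifier(FAST, 3, ["a", "b"])
        with pytest.raises(ValueError, match="b"):
            model.fit(X, np.array(["a"] * 4))

    def test_single_class_train_raises(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array(["a"] * 10)
        with pytest.raises(ValueError):
            classify.train_mlp(X, y, FAST)

    def test_wellmixed_features_near_chance(self, rng):
        # indistinguishable classes: accuracy should be near chance, not high
        X = rng.standard_normal((120, 6))
        y = np.array(["a", "b", "c"] * 40)
        _, conf = classify.train_mlp(X, y, FAST)
        m = conf.to_numpy()
        acc = np.trace(m) / m.sum()
        assert acc < 0.65

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            MLPSpec(hidden_sizes=(0,))
        with pytest.raises(ValueError):
            MLPSpec(dropout=1.0)


class TestGrouping:
    def test_default_merges(self):
        g = default_grouping()
        assert g.merged("P5") == g.merged("P6") == "P5+P6"
        assert g.merged("P7") == g.merged("P8") == "P7+P8"
        assert g.merged("P0") == "P0"

    def test_stage_map_total(self):
        g = default_grouping()
        for code in ("P0", "P1", "P3", "P5", "P7", "P9", "P10"):
            assert g.stage(g.merged(code)) in ("non-tumor", "DCIS", "IDC")

    def test_error_types_enumeration(self):
        assert len(classify.ERROR_TYPES) == 6
        assert "non-tumor->DCIS" in classify.ERROR_TYPES


class TestLopoCV:
    def test_two_patients_two_folds_every_sample_once(self, rng):
        X, y, pids, sids = _signal_cohort(rng, n_patients=2)
        cv = classify.lopo_cv(X, y, pids, FAST, sample_ids=sids)
        assert len(cv.y_pred) == len(y)
        assert cv.confusion.to_numpy().sum() == len(y)

    def test_no_patient_leakage_structure(self, rng):
        # leakage is asserted inside lopo_cv; also verify fold coverage here
        X, y, pids, sids = _signal_cohort(rng)
        cv = classify.lopo_cv(X, y, pids, FAST, sample_ids=sids)
        assert set(cv.sample_ids) == set(sids)

    def test_planted_signal_beats_chance(self, rng):
        X, y, pids, sids = _signal_cohort(rng, n_patients=8)
        cv = classify.lopo_cv(X, y, pids, FAST, sample_ids=sids)
        accuracy = 1.0 - cv.error_rate
        assert accuracy > 2.0 / len(set(y))

    def test_fewer_than_two_patients_raises(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            classify.lopo_cv(X, ["P0", "P5", "P0", "P5"], ["p1"] * 4, FAST)

    def test_single_patient_class_warned_and_excluded(self, rng):
        X = np.concatenate([rng.normal(-3, 0.2, (6, 4)), rng.normal(3, 0.2, (6, 4))])
        y = ["P0"] * 6 + ["P10"] * 6
        pids = ["a", "a", "b", "b", "c", "c"] + ["d", "d", "e", "e", "f", "f"]
        y[0] = "P3"  # P3 confined to patient a
        with pytest.warns(UserWarning, match="P3"):
            cv = classify.lopo_cv(X, y, pids, FAST)
        assert "P3" in cv.excluded_classes
        assert "P3" not in cv.per_class_error


def _spatial_cohort(rng, c7_by_cat, n_patients=9, cells=90, size=420):
    """Cohorts whose only category signal is the cluster-7 share."""
    cats = list(c7_by_cat)
    samples = []
    k = 0
    for p in range(n_patients):
        for _ in range(2):
            cat = cats[k % len(cats)]
            c7 = c7_by_cat[cat]
            props = np.full(8, (1 - c7) / 7)
            props[7] = c7
            labels = rng.choice(8, size=cells, p=props)
            cents = rng.uniform(0, size, size=(cells, 2))
            samples.append(
                SampleSpatial(
                    sample_id=f"s{k}", patient_id=f"pat{p}", category=cat,
                    centroids=cents, labels=labels, area_px2=float(size * size),
                )
            )
            k += 1
    return samples


class TestAblation:
    def test_nine_rows(self, rng):
        samples = _spatial_cohort(rng, {"P0": 0.05, "P10": 0.45}, n_patients=4,
                                  cells=40)
        spec = MLPSpec(hidden_sizes=(16, 16, 16), epochs=40, patience=10, seed=0)
        df = classify.ablation_study(samples, spec, radius_um=40.0)
        assert len(df) == 9
        assert df["ablated"].tolist() == ["None"] + [str(k) for k in range(8)]

    def test_ablating_absent_cluster_matches_baseline(self, rng):
        samples = _spatial_cohort(rng, {"P0": 0.05, "P10": 0.45}, n_patients=4,
                                  cells=40)
        for s in samples:
            s.labels = np.where(s.labels == 2, 1, s.labels)  # cluster 2 absent
        X_base, _, _, _ = classify.build_representations(samples, radius_um=40.0)
        X_abl, _, _, _ = classify.build_representations(samples, radius_um=40.0,
                                                        ablate=2)
        # identical cells used; the ablated representation just drops the
        # empty row/column, so the retained entries agree
        keep = [i for i in range(8) if i != 2]
        base_mats = X_base[:, :64].reshape(-1, 8, 8)[:, keep][:, :, keep]
        abl_mats = X_abl[:, :49].reshape(-1, 7, 7)
        np.testing.assert_allclose(base_mats, abl_mats, atol=1e-9)

    def test_signal_cluster_ablation_degrades(self, rng):
        samples = _spatial_cohort(
            rng, {"P0": 0.04, "P5": 0.18, "P10": 0.45}, n_patients=9, cells=90
        )
        spec = MLPSpec(hidden_sizes=(32, 32, 32), epochs=120, patience=20, seed=1)
        X, kept, _, _ = classify.build_representations(samples, radius_um=40.0)
        cv_base = classify.lopo_cv(
            X, [s.category for s in samples], [s.patient_id for s in samples],
            spec, sample_ids=[s.sample_id for s in samples],
        )
        X7, kept7, _, _ = classify.build_representations(samples, radius_um=40.0,
                                                         ablate=7)
        sub = [samples[i] for i in kept7]
        cv_abl = classify.lopo_cv(
            X7, [s.category for s in sub], [s.patient_id for s in sub],
            spec, sample_ids=[s.sample_id for s in sub],
        )
        assert cv_abl.error_rate > cv_base.error_rate


class TestContrast:
    def _toy_cv(self):
        y_true = np.array(["P0", "P0", "P10", "P10"])
        y_pred = np.array(["P0", "P10", "P10", "P10"])
        g = default_grouping()
        return classify.CVResult(
            y_true=y_true, y_pred=y_pred,
            patient_ids=np.array(["a", "b", "c", "d"]),
            sample_ids=np.array(["s0", "s1", "s2", "s3"]),
            classes=["P0", "P10"],
            confusion=classify.confusion_table(y_true, y_pred, ["P0", "P10"]),
            error_rate=0.25, per_class_error={}, stage_errors={}, stage_error_rate=0.25,
        )

    def test_identical_groups_zero_log2fc(self):
        cv = self._toy_cv()
        mat = np.full((8, 8), 0.125)
        props = np.full(8, 0.125)
        mats = {sid: mat for sid in cv.sample_ids}
        prps = {sid: props for sid in cv.sample_ids}
        out = classify.misclassification_contrast(cv, mats, prps)
        assert "non-tumor->IDC" in out
        np.testing.assert_allclose(out["non-tumor->IDC"]["coloc_log2fc"], 0.0)
        np.testing.assert_allclose(out["non-tumor->IDC"]["proportion_log2fc"], 0.0)

    def test_doubled_cluster7_proportion_log2fc_one(self):
        cv = self._toy_cv()
        base = np.full(8, 0.1)
        doubled = base.copy()
        doubled[7] = 0.2
        prps = {"s0": base, "s1": doubled, "s2": base, "s3": base}
        mats = {sid: np.full((8, 8), 0.125) for sid in cv.sample_ids}
        out = classify.misclassification_contrast(cv, mats, prps)
        assert out["non-tumor->IDC"]["proportion_log2fc"][7] == pytest.approx(1.0)

    def test_keys_are_true_arrow_predicted(self):
        cv = self._toy_cv()
        mats = {sid: np.full((8, 8), 0.125) for sid in cv.sample_ids}
        prps = {sid: np.full(8, 0.125) for sid in cv.sample_ids}
        out = classify.misclassification_contrast(cv, mats, prps)
        for key in out:
            assert key in classify.ERROR_TYPES


class TestSubset:
    def test_single_class_subset_raises(self, rng):
        samples = _spatial_cohort(rng, {"P0": 0.05, "P10": 0.45}, n_patients=4,
                                  cells=40)
        with pytest.raises(ValueError):
            classify.subset_classifier(samples, ["P0"], FAST)

    def test_subset_isolated_from_outside_samples(self, rng):
        samples = _spatial_cohort(
            rng, {"P0": 0.04, "P5": 0.25, "P10": 0.5}, n_patients=6, cells=60
        )
        spec = MLPSpec(hidden_sizes=(16, 16, 16), epochs=60, patience=10, seed=0)
        sub_only = [s for s in samples if s.category in ("P0", "P5")]
        a = classify.subset_classifier(samples, ["P0", "P5"], spec, radius_um=40.0)
        b = classify.subset_classifier(sub_only, ["P0", "P5"], spec, radius_um=40.0)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)

    def test_separable_subset_diagonal_dominant(self, rng):
        samples = _spatial_cohort(
            rng, {"P0": 0.03, "P3": 0.18, "P5": 0.38, "P10": 0.6},
            n_patients=12, cells=150,
        )
        spec = MLPSpec(hidden_sizes=(32, 32, 32), epochs=300, seed=0)
        cv = classify.subset_classifier(samples, ["P0", "P3", "P5", "P10"], spec,
                                        radius_um=40.0)
        m = cv.confusion.to_numpy()
        # well above the 25% chance diagonal for 4 balanced classes
        assert np.trace(m) >= m.sum() / 2


class TestFoldAndInputVariants:
    def test_leave_one_sample_out_mode(self, rng):
        X, y, pids, sids = _signal_cohort(rng, n_patients=4)
        cv = classify.lopo_cv(X, y, pids, FAST, sample_ids=sids, fold_on="sample")
        assert len(cv.y_pred) == len(y)
        assert cv.confusion.to_numpy().sum() == len(y)

    def test_ductal_only_restriction(self, rng):
        samples = _spatial_cohort(rng, {"P0": 0.05, "P10": 0.45}, n_patients=4,
                                  cells=60)
        flags = {
            s.sample_id: np.arange(len(s.labels)) % 2 == 0 for s in samples
        }
        X_all, _, _, _ = classify.build_representations(samples, radius_um=40.0)
        X_duct, kept, _, _ = classify.build_representations(
            samples, radius_um=40.0, ductal_only_flags=flags
        )
        assert X_duct.shape[1] == X_all.shape[1]
        assert len(kept) == len(samples)
        assert not np.allclose(X_all, X_duct)


class TestBaselines:
    def test_logistic_baseline_runs_and_scores(self, rng):
        X, y, pids, sids = _signal_cohort(rng)
        cv = classify.logistic_baseline(X, y, pids, sample_ids=sids)
        assert cv.confusion.to_numpy().sum() == len(y)
        assert 1.0 - cv.error_rate > 0.5  # strong planted signal

    def test_input_variant_modes_same_machinery(self, rng):
        samples = _spatial_cohort(rng, {"P0": 0.05, "P10": 0.45}, n_patients=4,
                                  cells=40)
        for mode, dim in (("coloc", 65), ("props", 9), ("both", 73)):
            X, kept, _, _ = classify.build_representations(
                samples, radius_um=40.0, mode=mode
            )
            assert X.shape == (len(kept), dim)
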