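"""Phenotype classifiers over sample-level co-localization features:
MLP training with inverse-class-frequency weighting, leave-one-patient-out
cross-validation, category grouping and stage-level error types, cluster
ablation, misclassification contrasts, and a logistic-regression baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn, spatial
from ._nn import Adam, Dense, Dropout, LeakyReLU, Sequential, weighted_cross_entropy
from .synth import CATEGORY_STAGE, STAGES


@dataclass
class MLPSpec:
    hidden_sizes: tuple[int, ...] = (64, 64, 64)
    dropout: float = 0.5
    activation_slope: float = 0.01
    epochs: int = 300
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2  # desk-scale cohorts are tiny; regularize
    batch_size: int = 32
    val_fraction: float = 0.15
    patience: int = 40
    seed: int = 0

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class CategoryGrouping:
    """Total map from P-codes to merged class labels plus a stage map used
    for the 6 stage-transition error types."""

    merge_map: dict[str, str]
    stage_map: dict[str, str]

    def merged(self, category: str) -> str:
        return self.merge_map[category]

    def stage(self, merged_label: str) -> str:
        return self.stage_map[merged_label]


def default_grouping() -> CategoryGrouping:
    """Ships the two standard merges (P5+P6 and P7+P8); other categories
    keep their own code as class label."""
    merge = {c: c for c in CATEGORY_STAGE}
    merge["P5"] = merge["P6"] = "P5+P6"
    merge["P7"] = merge["P8"] = "P7+P8"
    stage = {}
    for code, label in merge.items():
        stage[label] = CATEGORY_STAGE[code]
    return CategoryGrouping(merge_map=merge, stage_map=stage)


ERROR_TYPES = tuple(
    f"{t}->{p}" for t in STAGES for p in STAGES if t != p
)


@dataclass
class CVResult:
    y_true: np.ndarray  # merged class labels (strings)
    y_pred: np.ndarray
    patient_ids: np.ndarray
    sample_ids: np.ndarray
    classes: list[str]
    confusion: pd.DataFrame  # rows = truth, columns = prediction (counts)
    error_rate: float
    per_class_error: dict[str, float]
    stage_errors: dict[str, int]  # 6 stage-transition error-type counts
    stage_error_rate: float
    excluded_classes: list[str] = field(default_factory=list)

    def confusion_normalized(self) -> pd.DataFrame:
        m = self.confusion.to_numpy(dtype=float)
        s = m.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            np.divide(m, s, out=np.zeros_like(m), where=s > 0),
            index=self.confusion.index,
            columns=self.confusion.columns,
        )


# ---------------------------------------------------------------------------
# MLP


class MLPClassifier:
    """3-hidden-layer MLP with leaky-rectifier activations, dropout, and
    inverse-class-frequency weighted cross-entropy, trained with Adam and
    early stopping on a small validation split."""

    def __init__(self, spec: MLPSpec, n_features: int, classes):
        self.spec = spec
        self.classes = list(classes)
        rng = np.random.default_rng(spec.seed)
        self._drop_rng = np.random.default_rng(spec.seed + 7)
        layers = []
        d = n_features
        for h in spec.hidden_sizes:
            layers += [
                Dense(d, h, rng),
                LeakyReLU(spec.activation_slope),
                Dropout(spec.dropout, self._drop_rng),
            ]
            d = h
        layers.append(Dense(d, len(self.classes), rng))
        self.net = Sequential(*layers)
        self._mean = np.zeros(n_features, dtype=_nn.DTYPE)
        self._scale = np.ones(n_features, dtype=_nn.DTYPE)

    def _encode_y(self, y) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        missing = set(np.unique(y)) - set(lut)
        if missing:
            raise ValueError(f"labels not in training classes: {sorted(missing)}")
        return np.array([lut[v] for v in y], dtype=int)

    def fit(self, X, y):
        spec = self.spec
        X = np.asarray(X, dtype=np.float64)
        yi = self._encode_y(y)
        present = np.unique(yi)
        absent = [self.classes[i] for i in range(len(self.classes)) if i not in present]
        if absent:
            raise ValueError(f"class absent from training split: {absent}")
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._scale = np.where(sd > 1e-12, sd, 1.0)
        Xs = ((X - self._mean) / self._scale).astype(_nn.DTYPE)

        counts = np.bincount(yi, minlength=len(self.classes)).astype(float)
        weights = np.zeros(len(self.classes))
        weights[counts > 0] = 1.0 / counts[counts > 0]
        weights *= len(weights[counts > 0]) / weights.sum()  # mean-1 scaling

        rng = np.random.default_rng(spec.seed + 1)
        n = len(Xs)
        # validation-based model selection is counterproductive on a handful
        # of samples; require a minimally informative split
        n_val = int(round(spec.val_fraction * n))
        if n_val < 6:
            n_val = 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = Adam(self.net, lr=spec.learning_rate, weight_decay=spec.weight_decay)
        best_val, best_w, since = np.inf, _nn.get_weights(self.net), 0
        for _epoch in range(spec.epochs):
            order = rng.permutation(tr_idx)
            for start in range(0, len(order), spec.batch_size):
                idx = order[start : start + spec.batch_size]
                if len(idx) == 0:
                    continue
                opt.zero_grad()
                logits = self.net.forward(Xs[idx], train=True)
                _, g = weighted_cross_entropy(logits, yi[idx], weights)
                self.net.backward(g)
                opt.step()
            if n_val:
                logits = self.net.forward(Xs[val_idx], train=False)
                vloss, _ = weighted_cross_entropy(logits, yi[val_idx], weights)
                if vloss < best_val - 1e-6:
                    best_val, best_w, since = vloss, _nn.get_weights(self.net), 0
                else:
                    since += 1
                    if since >= spec.patience:
                        break
        if n_val:
            _nn.set_weights(self.net, best_w)
        return self

    def predict_logits(self, X) -> np.ndarray:
        Xs = ((np.asarray(X, dtype=np.float64) - self._mean) / self._scale).astype(
            _nn.DTYPE
        )
        return self.net.forward(Xs, train=False)

    def predict(self, X) -> np.ndarray:
        idx = self.predict_logits(X).argmax(axis=1)
        return np.array([self.classes[i] for i in idx])


def inverse_frequency_weights(y) -> dict:
    """Per-class loss weights proportional to inverse class counts."""
    vals, counts = np.unique(y, return_counts=True)
    return {v: 1.0 / c for v, c in zip(vals, counts)}


def train_mlp(X, y, spec: MLPSpec, splits=None):
    """Train an MLP and return ``(model, test-split confusion DataFrame)``.

    ``splits`` is an optional (train_idx, test_idx) pair; by default a seeded
    80/20 split is used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if splits is None:
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(len(y))
        n_test = max(1, len(y) // 5)
        splits = (perm[n_test:], perm[:n_test])
    tr, te = splits
    classes = sorted(set(np.asarray(y).tolist()))
    if len(np.unique(y[tr])) < 2:
        raise ValueError("need >= 2 classes in the training split")
    model = MLPClassifier(spec, X.shape[1], classes).fit(X[tr], y[tr])
    pred = model.predict(X[te])
    conf = confusion_table(y[te], pred, classes)
    return model, conf


def confusion_table(y_true, y_pred, classes) -> pd.DataFrame:
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    lut = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        mat[lut[t], lut[p]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


# ---------------------------------------------------------------------------
# Leave-one-patient-out CV


def lopo_cv(
    X,
    categories,
    patient_ids,
    mlp_spec: MLPSpec | None = None,
    grouping: CategoryGrouping | None = None,
    sample_ids=None,
    fold_on: str = "patient",
) -> CVResult:
    """Leave-one-patient-out (or leave-one-sample-out) cross-validation.

    Every sample is predicted exactly once; train/test patient sets are
    disjoint in every fold by construction (asserted).
    """
    X = np.asarray(X, dtype=float)
    categories = np.asarray(categories)
    patient_ids = np.asarray(patient_ids)
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(len(X))])
    sample_ids = np.asarray(sample_ids)
    grouping = grouping or default_grouping()
    spec = mlp_spec or MLPSpec()
    y = np.array([grouping.merged(c) for c in categories])
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("degenerate task: fewer than 2 merged classes")

    # classes confined to a single patient cannot be scored fairly
    excluded = []
    for cls in classes:
        n_pat = len(np.unique(patient_ids[y == cls]))
        if n_pat < 2:
            warnings.warn(
                f"class {cls!r} present in only {n_pat} patient(s); "
                "excluded from per-class error",
                stacklevel=2,
            )
            excluded.append(cls)

    units = np.unique(patient_ids if fold_on == "patient" else sample_ids)
    if fold_on == "patient" and len(units) < 2:
        raise ValueError("need >= 2 patients for leave-one-patient-out CV")
    y_pred = np.empty(len(y), dtype=object)
    master = np.random.default_rng(spec.seed)
    for unit in units:
        test = (patient_ids if fold_on == "patient" else sample_ids) == unit
        train = ~test
        assert not (
            set(patient_ids[train]) & set(patient_ids[test])
        ) or fold_on != "patient", "patient leakage in fold"
        fold_spec = MLPSpec(
            **{
                **spec.__dict__,
                "seed": int(master.integers(0, 2**31 - 1)),
            }
        )
        fold_classes = sorted(set(y[train].tolist()))
        model = MLPClassifier(fold_spec, X.shape[1], fold_classes).fit(
            X[train], y[train]
        )
        y_pred[test] = model.predict(X[test])
    y_pred = y_pred.astype(str)

    conf = confusion_table(y, y_pred, classes)
    error_rate = float((y != y_pred).mean())
    per_class = {}
    for cls in classes:
        if cls in excluded:
            continue
        sel = y == cls
        per_class[cls] = float((y_pred[sel] != cls).mean()) if sel.any() else np.nan
    stage_true = np.array([grouping.stage(v) for v in y])
    stage_pred = np.array([grouping.stage(v) for v in y_pred])
    stage_errors = {et: 0 for et in ERROR_TYPES}
    for t, p in zip(stage_true, stage_pred):
        if t != p:
            stage_errors[f"{t}->{p}"] += 1
    return CVResult(
        y_true=y,
        y_pred=y_pred,
        patient_ids=patient_ids,
        sample_ids=sample_ids,
        classes=classes,
        confusion=conf,
        error_rate=error_rate,
        per_class_error=per_class,
        stage_errors=stage_errors,
        stage_error_rate=float((stage_true != stage_pred).mean()),
        excluded_classes=excluded,
    )


# ---------------------------------------------------------------------------
# Sample-level spatial features and the ablation study


@dataclass
class SampleSpatial:
    """Per-sample inputs for co-localization representations."""

    sample_id: str
    patient_id: str
    category: str
    centroids: np.ndarray
    labels: np.ndarray  # cluster ids 0..7
    area_px2: float


def build_representations(
    samples: list[SampleSpatial],
    radius_um: float = spatial.DEFAULT_RADIUS_UM,
    pixel_size_um: float = spatial.DEFAULT_PIXEL_SIZE_UM,
    mode: str = "coloc",
    ablate: int | None = None,
    ductal_only_flags: dict[str, np.ndarray] | None = None,
):
    """Feature matrix (and matrices/proportions) for a list of samples.

    ``ablate=k`` removes cluster-k cells before computing the matrices and
    returns the 7x7 representation. ``ductal_only_flags`` optionally maps
    sample_id to a boolean in-duct mask restricting the cells used.
    """
    rows, mats, props_all = [], {}, {}
    for s in samples:
        cent, lab = np.asarray(s.centroids, float), np.asarray(s.labels, int)
        if ductal_only_flags is not None:
            keep = np.asarray(ductal_only_flags[s.sample_id], bool)
            cent, lab = cent[keep], lab[keep]
        if ablate is not None:
            keep = lab != ablate
            cent, lab = cent[keep], lab[keep]
        if len(lab) == 0:
            rows.append(None)
            continue
        counts = spatial.neighborhood_counts(cent, lab, radius_um, pixel_size_um)
        mat = spatial.coloc_matrix(
            counts, lab, radius_um, pixel_size_um, area_px2=s.area_px2,
            sample_id=s.sample_id,
        )
        props = np.bincount(lab, minlength=spatial.N_CLUSTERS) / len(lab)
        rows.append(spatial.sample_representation(mat, props, mode=mode, ablate=ablate))
        mats[s.sample_id] = mat.matrix
        props_all[s.sample_id] = props
    kept = [i for i, r in enumerate(rows) if r is not None]
    X = np.array([rows[i] for i in kept])
    return X, kept, mats, props_all


def ablation_study(
    samples: list[SampleSpatial],
    mlp_spec: MLPSpec | None = None,
    grouping: CategoryGrouping | None = None,
    radius_um: float = spatial.DEFAULT_RADIUS_UM,
    pixel_size_um: float = spatial.DEFAULT_PIXEL_SIZE_UM,
) -> pd.DataFrame:
    """Baseline ("None") plus one LOPO CV per ablated cluster 0..7.

    Returns a 9-row table of overall error, stage error, and the 6
    stage-transition error-type counts.
    """
    rows = []
    results = {}
    for ablate in [None] + list(range(spatial.N_CLUSTERS)):
        X, kept, _, _ = build_representations(
            samples, radius_um, pixel_size_um, mode="coloc", ablate=ablate
        )
        if len(kept) < len(samples):
            warnings.warn(
                f"ablation {ablate}: {len(samples) - len(kept)} sample(s) emptied "
                "and excluded",
                stacklevel=2,
            )
        sub = [samples[i] for i in kept]
        cv = lopo_cv(
            X,
            [s.category for s in sub],
            [s.patient_id for s in sub],
            mlp_spec,
            grouping,
            sample_ids=[s.sample_id for s in sub],
        )
        results[ablate] = cv
        row = {
            "ablated": "None" if ablate is None else str(ablate),
            "error_rate": cv.error_rate,
            "stage_error_rate": cv.stage_error_rate,
            "n_samples": len(sub),
        }
        row.update(cv.stage_errors)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["cv_results"] = results
    return df


def misclassification_contrast(
    cv: CVResult,
    matrices: dict[str, np.ndarray],
    proportions: dict[str, np.ndarray],
    grouping: CategoryGrouping | None = None,
) -> dict[str, dict]:
    """Per stage-transition error type, log2 fold change of mean
    co-localization matrices and %cluster proportions, misclassified vs
    correctly classified samples of the same true stage.
    """
    grouping = grouping or default_grouping()
    stage_true = np.array([grouping.stage(v) for v in cv.y_true])
    stage_pred = np.array([grouping.stage(v) for v in cv.y_pred])
    out: dict[str, dict] = {}
    for et in ERROR_TYPES:
        t, p = et.split("->")
        mis = (stage_true == t) & (stage_pred == p)
        correct = (stage_true == t) & (stage_pred == t)
        if not mis.any() or not correct.any():
            continue  # skipped with log entry
        def _mean_mat(sel):
            return np.nanmean(
                np.stack([matrices[sid] for sid in cv.sample_ids[sel]]), axis=0
            )

        def _mean_props(sel):
            return np.mean(
                np.stack([proportions[sid] for sid in cv.sample_ids[sel]]), axis=0
            )

        with np.errstate(divide="ignore", invalid="ignore"):
            mat_fc = np.log2(_mean_mat(mis) / _mean_mat(correct))
            prop_fc = np.log2(_mean_props(mis) / _mean_props(correct))
        out[et] = {
            "coloc_log2fc": mat_fc,
            "proportion_log2fc": prop_fc,
            "n_misclassified": int(mis.sum()),
            "n_correct": int(correct.sum()),
        }
    return out


def subset_classifier(
    samples: list[SampleSpatial],
    categories_subset,
    mlp_spec: MLPSpec | None = None,
    grouping: CategoryGrouping | None = None,
    radius_um: float = spatial.DEFAULT_RADIUS_UM,
    pixel_size_um: float = spatial.DEFAULT_PIXEL_SIZE_UM,
    mode: str = "coloc",
) -> CVResult:
    """Restrict the cohort to a category subset and run LOPO CV."""
    grouping = grouping or default_grouping()
    subset = set(categories_subset)
    keep = [s for s in samples if s.category in subset or grouping.merged(s.category) in subset]
    merged = {grouping.merged(s.category) for s in keep}
    if len(merged) < 2:
        raise ValueError("degenerate task: subset spans fewer than 2 classes")
    X, kept, _, _ = build_representations(keep, radius_um, pixel_size_um, mode=mode)
    sub = [keep[i] for i in kept]
    return lopo_cv(
        X,
        [s.category for s in sub],
        [s.patient_id for s in sub],
        mlp_spec,
        grouping,
        sample_ids=[s.sample_id for s in sub],
    )


def logistic_baseline(
    X, categories, patient_ids, grouping: CategoryGrouping | None = None,
    sample_ids=None, seed: int = 0,
) -> CVResult:
    """LOPO CV with a multinomial logistic regression (comparison baseline)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, dtype=float)
    categories = np.asarray(categories)
    patient_ids = np.asarray(patient_ids)
    grouping = grouping or default_grouping()
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(len(X))])
    sample_ids = np.asarray(sample_ids)
    y = np.array([grouping.merged(c) for c in categories])
    classes = sorted(set(y.tolist()))
    y_pred = np.empty(len(y), dtype=object)
    for unit in np.unique(patient_ids):
        test = patient_ids == unit
        scaler = StandardScaler().fit(X[~test])
        clf = LogisticRegression(max_iter=2000, class_weight="balanced", random_state=seed)
        clf.fit(scaler.transform(X[~test]), y[~test])
        y_pred[test] = clf.predict(scaler.transform(X[test]))
    y_pred = y_pred.astype(str)
    conf = confusion_table(y, y_pred, classes)
    stage_true = np.array([grouping.stage(v) for v in y])
    stage_pred = np.array([grouping.stage(v) for v in y_pred])
    stage_errors = {et: 0 for et in ERROR_TYPES}
    for t, p in zip(stage_true, stage_pred):
        if t != p:
            stage_errors[f"{t}->{p}"] += 1
    return CVResult(
        y_true=y,
        y_pred=y_pred,
        patient_ids=patient_ids,
        sample_ids=sample_ids,
        classes=classes,
        confusion=conf,
        error_rate=float((y != y_pred).mean()),
        per_class_error={
            c: float((y_pred[y == c] != c).mean()) for c in classes if (y == c).any()
        },
        stage_errors=stage_errors,
        stage_error_rate=float((stage_true != stage_pred).mean()),
    )
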