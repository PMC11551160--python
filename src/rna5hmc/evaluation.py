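"""Performance evaluation: confusion-matrix metrics, ROC/AUC, stratified
K-fold cross-validation and the ablation/comparison harness.

Metric conventions follow the modification-site prediction literature:
accuracy, sensitivity and specificity are reported as percentages; the
Matthews correlation coefficient (MCC) on its natural [-1, 1] scale;
recall and F1 as proportions (F1 is conventionally also quoted x100 in
comparison tables). Zero-denominator ratios are reported as NaN with a
warning, never silently as 0 — a silent zero would corrupt grid-search
selection.

The cross-validation driver fits PCA inside each fold (training rows
only) so dimensionality reduction never sees held-out data; a ``pooled``
flag reproduces the leaky pooled-fit variant for comparison. Baseline
classifiers (NB/SVM/KNN/RF/DT) are thin adapters over scikit-learn for
comparison tables — non-novel glue behind a uniform fit/predict contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoders import ENCODER_NAMES, EncoderConfig
from .feature_pipeline import (
    FeatureMatrix,
    encode_dataset,
    fit_pca,
    transform_pca,
)
from .dnn import DnnConfig, DnnModel, classify, predict_proba, train_dnn
from .sequence_io import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CvResult",
    "confusion",
    "compute_metrics",
    "roc_curve_auc",
    "stratified_kfold",
    "run_cv",
    "run_ablation",
    "make_baseline",
    "BASELINE_NAMES",
    "train_full",
    "evaluate_independent",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")


@dataclass
class MetricSet:
    """One evaluation's metrics. accuracy/sensitivity/specificity are
    percentages; mcc in [-1, 1]; recall/f1/auc proportions in [0, 1]."""

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    recall: float
    f1: float
    auc: float | None = None

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(labels, predictions) -> ConfusionCounts:
    """Standard 2x2 tally; tp counts label=1 and prediction=1."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.ndim != 1 or len(y) < 1:
        raise ValueError(
            f"labels {y.shape} and predictions {p.shape} must be equal-length "
            "1-D vectors of length >= 1"
        )
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity (x100), MCC, recall and F1 from
    a confusion tally.

        Acc = (TP + TN) / (TP + FP + FN + TN) * 100
        Sn  = TP / (TP + FN) * 100        (= recall * 100)
        Sp  = TN / (TN + FP) * 100
        MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
        F1  = 2 * precision * recall / (precision + recall)
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    n = tp + tn + fp + fn
    acc = (tp + tn) / n * 100.0
    recall = _ratio(tp, tp + fn, "sensitivity/recall")
    sn = recall * 100.0
    sp = _ratio(tn, tn + fp, "specificity") * 100.0
    mcc_den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        warnings.warn("MCC undefined (zero denominator); reporting NaN",
                      stacklevel=2)
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
    precision = _ratio(tp, tp + fp, "precision")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        warnings.warn("F1 undefined; reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(acc, sn, sp, float(mcc), float(recall), float(f1))


def roc_curve_auc(labels, scores) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC curve and trapezoidal AUC.

    Equal scores are grouped into single threshold steps, so the AUC
    equals the Mann–Whitney pair-counting statistic with ties counted 1/2.
    Returns (points, auc) where points is an (m, 2) array of (fpr, tpr).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D vectors")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def stratified_kfold(
    data: LabeledDataset, folds: int, seed: int = 1234
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified K-fold index pairs (train, test) partitioning the
    dataset with per-fold class ratios within one sample of the global."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_neg, n_pos = data.class_counts()
    if min(n_neg, n_pos) < folds:
        raise ValueError(
            f"each class needs >= {folds} members; have {n_neg}/{n_pos}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [
        (train, test)
        for train, test in skf.split(np.zeros(len(data)), data.labels)
    ]


@dataclass
class CvResult:
    per_fold: list[MetricSet]
    mean: MetricSet
    folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [m.to_dict() for m in self.per_fold]
        df = pd.DataFrame(rows)
        df.index = [f"fold{i + 1}" for i in range(len(rows))]
        df.loc["mean"] = self.mean.to_dict()
        return df


def _aggregate(per_fold: list[MetricSet]) -> MetricSet:
    # nanmean: a metric undefined on one fold should not poison the mean
    vals = {}
    for f in fields(MetricSet):
        col = np.array(
            [np.nan if getattr(m, f.name) is None else getattr(m, f.name)
             for m in per_fold],
            dtype=float,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals[f.name] = float(np.nanmean(col))
    return MetricSet(**vals)


BASELINE_NAMES = ("nb", "svm", "knn", "rf", "dt")


def make_baseline(name: str, seed: int = 1234):
    """Thin scikit-learn adapters for the comparison harness (Naive Bayes,
    SVM, K-nearest-neighbours, random forest, decision tree). Non-novel
    glue; each exposes fit(X, y) / predict_proba-or-decision scores."""
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    factories = {
        "nb": lambda: GaussianNB(),
        "svm": lambda: CalibratedClassifierCV(
            SVC(random_state=seed), ensemble=False
        ),
        "knn": lambda: KNeighborsClassifier(),
        "rf": lambda: RandomForestClassifier(random_state=seed),
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
    }
    if name not in factories:
        raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")
    return factories[name]()


def _fold_scores(
    classifier: str,
    X_train: FeatureMatrix,
    y_train: np.ndarray,
    X_test: FeatureMatrix,
    model_cfg: DnnConfig,
    fold_seed: int,
) -> np.ndarray:
    if classifier == "dnn":
        from dataclasses import replace

        cfg = replace(model_cfg, seed=fold_seed)
        model = train_dnn(X_train, y_train, cfg)
        return predict_proba(model, X_test)
    est = make_baseline(classifier, seed=fold_seed)
    est.fit(X_train.values, y_train)
    return est.predict_proba(X_test.values)[:, 1]


def run_cv(
    data: LabeledDataset,
    encoder_cfg: EncoderConfig | None = None,
    use_pca: bool = True,
    n_components: int = 75,
    model_cfg: DnnConfig | None = None,
    folds: int = 10,
    seed: int = 1234,
    encoder: str | None = None,
    classifier: str = "dnn",
    pooled_pca: bool = False,
) -> CvResult:
    """Stratified K-fold cross-validation of the full pipeline.

    Per fold: encode train and test sequences, fit PCA on the training
    rows only (unless ``pooled_pca``, the leaky variant kept for
    comparison), train the classifier, evaluate on the test rows.
    ``encoder`` selects a single encoding scheme for ablation runs
    (default: full hybrid). ``classifier`` is "dnn" or one of the
    scikit-learn baselines.
    """
    encoder_cfg = encoder_cfg or EncoderConfig()
    model_cfg = model_cfg or DnnConfig()
    matrix = encode_dataset(data, encoder_cfg, only=encoder)
    if use_pca:
        bound = min(len(data) - len(data) // folds - 1, matrix.shape[1])
        if n_components > bound:
            raise ValueError(
                f"n_components={n_components} exceeds per-fold bound {bound}"
            )
    pooled_model = fit_pca(matrix, n_components) if (use_pca and pooled_pca) else None
    per_fold: list[MetricSet] = []
    for fold_i, (train_idx, test_idx) in enumerate(
        stratified_kfold(data, folds, seed)
    ):
        X_train = matrix.rows(train_idx)
        X_test = matrix.rows(test_idx)
        y_train = data.labels[train_idx]
        y_test = data.labels[test_idx]
        if use_pca:
            pca = pooled_model or fit_pca(X_train, n_components)
            X_train = transform_pca(pca, X_train)
            X_test = transform_pca(pca, X_test)
        try:
            scores = _fold_scores(
                classifier, X_train, y_train, X_test, model_cfg,
                fold_seed=seed + fold_i,
            )
        except Exception as e:
            raise RuntimeError(f"fold {fold_i + 1}/{folds} failed: {e}") from e
        preds = classify(scores)
        m = compute_metrics(confusion(y_test, preds))
        try:
            _, m.auc = roc_curve_auc(y_test, scores)
        except ValueError:
            m.auc = None
        per_fold.append(m)
    return CvResult(per_fold, _aggregate(per_fold), folds, seed)


def run_ablation(
    data: LabeledDataset,
    encoder_cfg: EncoderConfig | None = None,
    n_components: int = 75,
    model_cfg: DnnConfig | None = None,
    folds: int = 10,
    seed: int = 1234,
    classifier: str = "dnn",
) -> pd.DataFrame:
    """Per-encoder ablation: one row per encoding scheme plus the hybrid
    vector with and without PCA feature selection."""
    rows = []
    for name in ENCODER_NAMES:
        res = run_cv(
            data, encoder_cfg, use_pca=False, model_cfg=model_cfg,
            folds=folds, seed=seed, encoder=name, classifier=classifier,
        )
        rows.append({"method": name, **res.mean.to_dict()})
    for label, use_pca in (
        ("hybrid (without feature selection)", False),
        ("hybrid (with feature selection)", True),
    ):
        res = run_cv(
            data, encoder_cfg, use_pca=use_pca, n_components=n_components,
            model_cfg=model_cfg, folds=folds, seed=seed, classifier=classifier,
        )
        rows.append({"method": label, **res.mean.to_dict()})
    return pd.DataFrame(rows)


def train_full(
    train: LabeledDataset,
    encoder_cfg: EncoderConfig | None = None,
    use_pca: bool = True,
    n_components: int = 75,
    model_cfg: DnnConfig | None = None,
):
    """Fit the final pipeline (encode, PCA, network) on a full training
    set. Returns (model, pca) with pca None when feature selection is off."""
    encoder_cfg = encoder_cfg or EncoderConfig()
    matrix = encode_dataset(train, encoder_cfg)
    pca = None
    if use_pca:
        pca = fit_pca(matrix, n_components)
        matrix = transform_pca(pca, matrix)
    model = train_dnn(matrix, train.labels, model_cfg or DnnConfig())
    return model, pca


def evaluate_independent(
    model: DnnModel,
    pca,
    independent: LabeledDataset,
    encoder_cfg: EncoderConfig | None = None,
) -> MetricSet:
    """Evaluate a trained pipeline on a held-out set. Warns if any
    independent sequence id was seen during training."""
    if len(independent) == 0:
        raise ValueError("independent set is empty")
    if model.training_ids:
        overlap = set(model.training_ids) & set(independent.ids)
        if overlap:
            warnings.warn(
                f"{len(overlap)} independent id(s) overlap the training set "
                f"(e.g. {sorted(overlap)[:3]}); metrics will be optimistic"
            )
    matrix = encode_dataset(independent, encoder_cfg or EncoderConfig())
    if pca is not None:
        matrix = transform_pca(pca, matrix)
    scores = predict_proba(model, matrix)
    m = compute_metrics(confusion(independent.labels, classify(scores)))
    try:
        _, m.auc = roc_curve_auc(independent.labels, scores)
    except ValueError:
        m.auc = None
    return m
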