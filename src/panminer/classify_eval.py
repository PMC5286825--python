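"""Marker evaluation by repeated stratified cross-validation.

Gene, pathway and pathway-set markers are compared as classification
features under a common protocol: 4-fold stratified cross-validation
repeated 8 times with fresh random partitions, four standard classifiers
(kNN, linear SVM, random forest, Gaussian naive Bayes), and
sensitivity / specificity / accuracy reported in percent as mean (sd)
over repetitions.  Anything data-dependent in feature construction — the
CORG-style pathway-set combination, moderated-t gene selection — is refit
inside each training fold to avoid leaking test labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .activity import PathwayActivityProfile, moderated_t_test, pathway_set_activity
from .io_formats import CASE, OmicsMatrix
from .rulemining import PathwaySetMarker

CLASSIFIERS = ("knn", "svm", "rf", "naive_bayes")
MARKER_TYPES = ("genes", "pathways", "pathway_sets")

#: fixed classifier settings, recorded in every report
CLASSIFIER_SETTINGS = {
    "knn": {"n_neighbors": 3, "metric": "euclidean"},
    "svm": {"kernel": "linear", "C": 1.0},
    "rf": {"n_estimators": 500},
    "naive_bayes": {},
}


def make_classifier(name: str, seed: int = 0):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class ClassificationReport:
    """Per-repetition metrics for one classifier on one marker type."""

    classifier: str
    marker_type: str
    per_rep: pd.DataFrame  # columns sensitivity/specificity/accuracy (percent)
    confusion: list[dict]  # per repetition TP/FN/TN/FP pooled over folds
    metadata: dict = field(default_factory=dict)

    @property
    def accuracies(self) -> np.ndarray:
        return self.per_rep["accuracy"].to_numpy()

    def mean_sd(self, metric: str) -> tuple[float, float]:
        col = self.per_rep[metric]
        return float(col.mean()), float(col.std(ddof=1))

    def summary_row(self) -> dict:
        out = {"classifier": self.classifier, "markers": self.marker_type}
        for m in ("sensitivity", "specificity", "accuracy"):
            mean, sd = self.mean_sd(m)
            out[m] = f"{mean:.2f} ({sd:.2f})"
        return out


def confusion_metrics(predictions, truth) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent; case is positive."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int(((pred == 1) & (true == 1)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must appear in the truth vector")
    return (100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp),
            100.0 * (tp + tn) / true.size)


def select_gene_markers(matrix: OmicsMatrix, labels: Mapping[str, str],
                        fit_samples: Sequence[str],
                        p_threshold: float = 0.05,
                        fallback_top: int = 10) -> list[str]:
    """Differentially expressed genes on the fit samples (moderated t).

    If nothing passes the p threshold the ``fallback_top`` genes with the
    largest |t| are returned so a classifier can still be trained.
    """
    sub = matrix.values[list(fit_samples)]
    is_case = np.array([labels[s] == CASE for s in fit_samples])
    t, p = moderated_t_test(sub.to_numpy(dtype=float), is_case)
    genes = np.asarray(matrix.genes)
    hit = p < p_threshold
    if hit.any():
        return genes[hit].tolist()
    order = np.argsort(-np.abs(t))[:fallback_top]
    return genes[order].tolist()


def build_feature_matrix(marker_type: str, markers,
                         profile: PathwayActivityProfile | None,
                         matrix: OmicsMatrix | None,
                         labels: Mapping[str, str],
                         fit_samples: Sequence[str] | None = None,
                         ) -> pd.DataFrame:
    """Samples-by-features matrix for one marker type.

    * ``genes`` — ``markers`` is a list of gene symbols; features are their
      (normalized) expression rows.
    * ``pathways`` — ``markers`` is a list of pathway IDs; features are
      activity rows.
    * ``pathway_sets`` — ``markers`` is a list of :class:`PathwaySetMarker`
      (or signed itemsets); each feature is the combined pathway-set
      activity, with the combination fit on ``fit_samples`` only.
    """
    if marker_type == "genes":
        if matrix is None:
            raise ValueError("gene markers need the gene-level matrix")
        missing = [g for g in markers if g not in matrix.values.index]
        if missing:
            raise KeyError(f"unknown gene markers: {missing[:5]}")
        return matrix.values.loc[list(markers)].T
    if marker_type == "pathways":
        if profile is None:
            raise ValueError("pathway markers need an activity profile")
        missing = [p for p in markers if p not in profile.activities.index]
        if missing:
            raise KeyError(f"unknown pathway markers: {missing[:5]}")
        return profile.activities.loc[list(markers)].T
    if marker_type == "pathway_sets":
        if profile is None:
            raise ValueError("pathway-set markers need an activity profile")
        cols = {}
        for k, m in enumerate(markers):
            itemset = m.itemset if isinstance(m, PathwaySetMarker) else tuple(m)
            name = f"set{k + 1}:" + "|".join(itemset)
            cols[name] = pathway_set_activity(profile, labels, itemset,
                                              fit_samples=fit_samples)
        return pd.DataFrame(cols)
    raise ValueError(f"unknown marker type {marker_type!r}")


def cross_validate(features: pd.DataFrame | None,
                   labels: Mapping[str, str], classifier: str,
                   n_folds: int = 4, n_reps: int = 8, seed: int = 0,
                   builder: Callable[[Sequence[str]], pd.DataFrame] | None = None,
                   samples: Sequence[str] | None = None,
                   ) -> ClassificationReport:
    """Repeated stratified k-fold CV of one classifier.

    ``builder(train_samples)`` may be supplied to rebuild the feature
    matrix inside each training fold (it must return features for ALL
    samples but may only consult the training ones); otherwise the fixed
    ``features`` matrix is used.  Repetition ``r`` partitions with random
    state ``seed + r`` (r = 1..n_reps).
    """
    if features is None and builder is None:
        raise ValueError("provide features or a builder")
    if samples is None:
        samples = list(features.index)
    samples = list(samples)
    y = np.array([1 if labels[s] == CASE else 0 for s in samples])
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < n_folds:
            raise ValueError(
                f"class {cls} has {count} samples, fewer than {n_folds} folds")
    per_rep, confusion = [], []
    for rep in range(1, n_reps + 1):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + rep)
        pred = np.empty_like(y)
        for train_idx, test_idx in skf.split(np.zeros_like(y), y):
            train_samples = [samples[i] for i in train_idx]
            test_samples = [samples[i] for i in test_idx]
            if builder is not None:
                feats = builder(train_samples)
            else:
                feats = features
            x_train = feats.loc[train_samples].to_numpy(dtype=float)
            x_test = feats.loc[test_samples].to_numpy(dtype=float)
            clf = make_classifier(classifier, seed=seed + rep)
            clf.fit(x_train, y[train_idx])
            pred[test_idx] = clf.predict(x_test)
        sens, spec, acc = confusion_metrics(pred, y)
        per_rep.append({"sensitivity": sens, "specificity": spec,
                        "accuracy": acc})
        confusion.append({
            "TP": int(((pred == 1) & (y == 1)).sum()),
            "FN": int(((pred == 0) & (y == 1)).sum()),
            "TN": int(((pred == 0) & (y == 0)).sum()),
            "FP": int(((pred == 1) & (y == 0)).sum()),
        })
    report = ClassificationReport(
        classifier=classifier, marker_type="features",
        per_rep=pd.DataFrame(per_rep, index=range(1, n_reps + 1)),
        confusion=confusion,
        metadata={"n_folds": n_folds, "n_reps": n_reps, "seed": seed,
                  "settings": CLASSIFIER_SETTINGS[classifier]},
    )
    return report


def evaluate_markers(marker_type: str, markers,
                     profile: PathwayActivityProfile | None,
                     matrix: OmicsMatrix | None,
                     labels: Mapping[str, str], classifier: str,
                     n_folds: int = 4, n_reps: int = 8, seed: int = 0,
                     refit_in_folds: bool = True,
                     gene_p_threshold: float = 0.05) -> ClassificationReport:
    """End-to-end evaluation of one marker type with one classifier.

    With ``refit_in_folds`` (default) the data-dependent parts of feature
    construction are re-estimated on each training fold; otherwise the
    full-data features are reused across folds (the optimistic variant).
    """
    if marker_type == "genes" and markers is None:
        # fold-internal differential-expression selection
        def builder(train_samples):
            sel = select_gene_markers(matrix, labels, train_samples,
                                      p_threshold=gene_p_threshold)
            return build_feature_matrix("genes", sel, profile, matrix, labels)

        samples = matrix.samples
        report = cross_validate(None, labels, classifier, n_folds, n_reps,
                                seed, builder=builder, samples=samples)
    elif marker_type == "pathway_sets" and refit_in_folds:
        def builder(train_samples):
            return build_feature_matrix("pathway_sets", markers, profile,
                                        matrix, labels,
                                        fit_samples=train_samples)

        samples = profile.samples
        report = cross_validate(None, labels, classifier, n_folds, n_reps,
                                seed, builder=builder, samples=samples)
    else:
        feats = build_feature_matrix(marker_type, markers, profile, matrix,
                                     labels)
        report = cross_validate(feats, labels, classifier, n_folds, n_reps,
                                seed)
    report.marker_type = marker_type
    return report


def paired_ttest_accuracies(acc_a, acc_b) -> float:
    """Two-sided paired t-test p-value between repetition accuracies.

    Zero-variance paired differences (including identical vectors) are
    degenerate for the t statistic and reported as NaN.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of >=2 accuracies")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if d.any():
            warnings.warn("constant non-zero paired differences; "
                          "t statistic undefined, reporting NaN")
        return float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


def classification_table(reports: Sequence[ClassificationReport]) -> pd.DataFrame:
    """Stack reports into a mean (sd) table, one row per classifier/markers."""
    return pd.DataFrame([r.summary_row() for r in reports])
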