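"""KNN classification of subjects from their NCI time courses.

Feature vectors concatenate a subject's per-window NCI values for the ES
and ToM networks (2 x 151 = 302 features with the default grid).  A
k-nearest-neighbour classifier (k = 10, Euclidean distance, unweighted
majority vote, even-vote ties broken by the single nearest neighbour) is
evaluated by stratified five-fold cross-validation, repeated with fresh
fold assignments (1000 repetitions by default); reported metrics are the
mean and standard deviation over repetitions.  Significance is assessed by
a label-permutation test: each permutation shuffles the labels once, reruns
the identical repeated-CV procedure, and the p-value is
``(#(permuted >= original) + 1)/(n_permutations + 1)``.

The patient group is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .nci import NCISeries

__all__ = [
    "ClassifierReport",
    "build_feature_matrix",
    "knn_repeated_cv",
    "permutation_pvalue",
    "permutation_test",
]

METRICS = ("accuracy", "sensitivity", "specificity", "ppv_patient", "ppv_control")


@dataclass
class ClassifierReport:
    """Mean/sd per metric over repetitions, optional permutation p, config echo."""

    mean: dict
    sd: dict
    per_repetition: np.ndarray = field(repr=False)
    p_perm: dict | None = None
    config: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for i, m in enumerate(METRICS):
            out[m] = {"mean": self.mean[m], "sd": self.sd[m]}
            if self.p_perm is not None:
                out[m]["p_perm"] = self.p_perm[m]
        return out


def build_feature_matrix(
    nci_by_subject: Mapping[str, Mapping[str, NCISeries]],
    networks: Sequence[str],
    groups: Mapping[str, str],
    span: slice | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-window NCI values of the given networks into features.

    Parameters
    ----------
    nci_by_subject : mapping subject_id -> {network name -> NCISeries}
    networks : ordered network names; features are concatenated in this order
    groups : mapping subject_id -> group label
    span : optional window slice restricting the features

    Returns ``(X, y, subject_ids)`` with ``X`` of shape
    (n_subjects, n_networks * span_length).  Degenerate (non-finite) NCI
    windows abort with an error naming the subject, since distance-based
    classification cannot tolerate missing features.
    """
    sel = span if span is not None else slice(None)
    rows, labels, ids = [], [], []
    for sid in sorted(nci_by_subject):
        parts = []
        for net in networks:
            series = nci_by_subject[sid][net]
            vals = series.values[sel]
            if not np.isfinite(vals).all():
                raise ValueError(
                    f"subject {sid} has degenerate NCI windows on {net}; "
                    "cannot build a complete feature vector"
                )
            parts.append(vals)
        rows.append(np.concatenate(parts))
        labels.append(groups[sid])
        ids.append(sid)
    return np.asarray(rows), np.asarray(labels), ids


def _knn_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    """Majority-vote KNN; even-vote ties fall back to the nearest neighbour."""
    k = min(k, len(x_train))
    dist = cdist(x_test, x_train)
    order = np.argsort(dist, axis=1)[:, :k]
    is_patient = (y_train == "patient")[order]
    votes = is_patient.sum(axis=1)
    pred = np.where(votes * 2 > k, "patient", "control")
    tied = votes * 2 == k
    if tied.any():
        pred[tied] = y_train[order[tied, 0]]
    return pred


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    pat = y_true == "patient"
    tp = np.sum(pat & (y_pred == "patient"))
    tn = np.sum(~pat & (y_pred == "control"))
    call_p = np.sum(y_pred == "patient")
    call_c = np.sum(y_pred == "control")
    return np.array([
        (tp + tn) / len(y_true),
        tp / pat.sum(),
        tn / (~pat).sum(),
        tp / call_p if call_p else np.nan,
        tn / call_c if call_c else np.nan,
    ])


def knn_repeated_cv(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    folds: int = 5,
    repetitions: int = 1000,
    rng: np.random.Generator | None = None,
) -> ClassifierReport:
    """Repeated stratified k-fold CV of the KNN classifier.

    Each repetition draws a fresh stratified fold assignment, pools the
    out-of-fold predictions, and computes accuracy, sensitivity (patients
    correctly classified / patients), specificity (controls correct /
    controls) and the per-class positive predictive values.
    """
    rng = np.random.default_rng(rng)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    counts = {lab: int(np.sum(labels == lab)) for lab in np.unique(labels)}
    if any(c < folds for c in counts.values()):
        raise ValueError(
            f"each class needs at least {folds} members for {folds}-fold CV; "
            f"got {counts}"
        )
    per_rep = np.empty((repetitions, len(METRICS)))
    for rep in range(repetitions):
        seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = np.empty(len(labels), dtype=labels.dtype)
        for train_idx, test_idx in skf.split(features, labels):
            pred[test_idx] = _knn_predict(
                features[train_idx], labels[train_idx], features[test_idx], k
            )
        per_rep[rep] = _metrics(labels, pred)
    mean, sd = {}, {}
    for i, m in enumerate(METRICS):
        col = per_rep[:, i]
        finite = col[np.isfinite(col)]
        mean[m] = float(finite.mean()) if finite.size else float("nan")
        sd[m] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    return ClassifierReport(
        mean=mean,
        sd=sd,
        per_repetition=per_rep,
        config={"k": k, "folds": folds, "repetitions": repetitions},
    )


def permutation_pvalue(
    original_metric: float, permuted_metrics: np.ndarray
) -> float:
    """``(#(permuted >= original) + 1) / (n_permutations + 1)``."""
    permuted = np.asarray(permuted_metrics, dtype=float)
    if permuted.size < 1:
        raise ValueError("need at least one permuted metric")
    return float((np.sum(permuted >= original_metric) + 1) / (permuted.size + 1))


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    folds: int = 5,
    repetitions: int = 1000,
    n_permutations: int = 1000,
    perm_repetitions: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClassifierReport:
    """Repeated-CV classification plus label-permutation significance.

    Labels are shuffled once per permutation and the identical repeated-CV
    procedure is rerun (optionally at a reduced repetition count,
    ``perm_repetitions``, to keep desk-scale runs tractable); the permuted
    mean metrics form the null for ``permutation_pvalue``.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    report = knn_repeated_cv(features, labels, k, folds, repetitions, rng)
    perm_reps = perm_repetitions if perm_repetitions is not None else repetitions
    null = np.empty((n_permutations, len(METRICS)))
    for i in range(n_permutations):
        shuffled = rng.permutation(labels)
        null_rep = knn_repeated_cv(features, shuffled, k, folds, perm_reps, rng)
        null[i] = [null_rep.mean[m] for m in METRICS]
    report.p_perm = {
        m: permutation_pvalue(report.mean[m], null[:, i])
        for i, m in enumerate(METRICS)
    }
    report.config.update(
        {"n_permutations": n_permutations, "perm_repetitions": perm_reps}
    )
    return report
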