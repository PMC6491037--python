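"""SVM cohort classification on pooled valid-edge connectivity features.

Features are the z-scored Fisher-z values of the valid edges, pooled
across all band maps and the Combined map.  Validation is a balanced
leave-one-out scheme: each iteration holds out one random case and one
random control, trains a linear SVM on an equal-sized random sample of
the remaining subjects per class, and scores the held-out pair; pooled
out-of-training scores give sensitivity, specificity and ROC AUC.
Significance versus chance comes from a label-permutation null of the
AUC, and cross-cohort transfer is evaluated with the reversed-label
convention (reversed AUC = 100 - AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .connectome import ConnMatrix, EdgeMask

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "pool_features",
    "loo_balanced_cv",
    "auc_permutation_p",
    "transfer_classify",
]

CASE, CONTROL = "case", "control"


@dataclass
class FeatureTable:
    """Subjects-by-features matrix of masked connectivity values."""

    subjects: list[str]
    labels: np.ndarray  # array of "case"/"control"
    features: np.ndarray  # (n_subjects, n_features)
    feature_index: list[tuple[str, int, int]]  # (band, i, j) per column

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")
        if self.features.shape != (len(self.subjects), len(self.feature_index)):
            raise ValueError("feature matrix shape does not match subjects/index")
        if len(set(self.feature_index)) != len(self.feature_index):
            raise ValueError("feature_index columns must be unique")
        bad = set(self.labels) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def n_case(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == CONTROL).sum())

    def with_labels(self, labels: np.ndarray) -> "FeatureTable":
        return replace(self, labels=np.asarray(labels))


@dataclass
class ClassifierReport:
    """Pooled out-of-training performance, all rates in percent."""

    sensitivity: float
    specificity: float
    auc: float
    n_iter: int
    seed: int | None
    p_perm: float | None = None
    extras: dict = field(default_factory=dict)


def pool_features(
    connectomes: Mapping[str, Sequence[ConnMatrix]],
    masks: Mapping[str, EdgeMask],
    subjects: Sequence[str],
    labels: Sequence[str],
) -> FeatureTable:
    """One feature column per (band, valid edge), values from each map.

    ``connectomes[band]`` must be aligned with ``subjects``.  Masks must
    have been computed over the pooled cohort (``scope == "pooled"``):
    masks estimated per group would leak the group structure into
    feature selection and bias classifier performance.
    """
    columns: list[np.ndarray] = []
    index: list[tuple[str, int, int]] = []
    for band, mask in masks.items():
        if mask.scope != "pooled":
            raise ValueError(
                f"mask for band {band!r} has scope {mask.scope!r}; classifier "
                "features require a pooled-cohort mask (leakage guard)"
            )
        conns = connectomes[band]
        if len(conns) != len(subjects):
            raise ValueError(f"band {band!r}: {len(conns)} maps for {len(subjects)} subjects")
        for c in conns:
            if c.n_nodes != mask.n_nodes:
                raise ValueError(f"band {band!r}: connectome/mask node mismatch")
        edges = mask.edge_list()
        vals = np.asarray([[c.z[i, j] for (i, j) in edges] for c in conns])
        columns.append(vals)
        index.extend((band, i, j) for i, j in edges)
    return FeatureTable(
        subjects=list(subjects),
        labels=np.asarray(labels),
        features=np.hstack(columns),
        feature_index=index,
    )


def _standardize(train: np.ndarray, *others: np.ndarray):
    """z-score by training-fold statistics only (constant columns pass through)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return tuple((x - mu) / sd for x in (train, *others))


def _fit_svm(x: np.ndarray, y: np.ndarray, C: float) -> SVC:
    clf = SVC(kernel="linear", C=C)
    clf.fit(x, y)
    return clf


def loo_balanced_cv(
    table: FeatureTable,
    train_per_class: int,
    n_iter: int = 5000,
    C: float = 1.0,
    seed: int | None = None,
) -> ClassifierReport:
    """Balanced leave-one-out SVM cross-validation.

    Each iteration: hold out one random case and one random control;
    train a linear SVM on ``train_per_class`` randomly chosen remaining
    subjects per class (balancing guards against the trivial
    majority-class solution in unbalanced cohorts); record the decision
    scores of the held-out pair.  Pooled scores yield the true-positive
    rate at the margin boundary (sensitivity), true-negative rate
    (specificity) and trapezoidal ROC AUC, all in percent.
    """
    case_idx = np.flatnonzero(table.labels == CASE)
    ctrl_idx = np.flatnonzero(table.labels == CONTROL)
    if len(case_idx) < train_per_class + 1 or len(ctrl_idx) < train_per_class + 1:
        raise ValueError(
            f"each class needs at least train_per_class+1={train_per_class + 1} "
            f"subjects (have {len(case_idx)} cases, {len(ctrl_idx)} controls)"
        )
    rng = np.random.default_rng(seed)
    scores: list[float] = []
    truth: list[int] = []
    for _ in range(n_iter):
        test_case = rng.choice(case_idx)
        test_ctrl = rng.choice(ctrl_idx)
        pool_case = case_idx[case_idx != test_case]
        pool_ctrl = ctrl_idx[ctrl_idx != test_ctrl]
        tr = np.concatenate(
            [
                rng.choice(pool_case, train_per_class, replace=False),
                rng.choice(pool_ctrl, train_per_class, replace=False),
            ]
        )
        assert tr.shape[0] == 2 * train_per_class  # balanced-training audit
        y = (table.labels[tr] == CASE).astype(int)
        x_tr, x_te = _standardize(
            table.features[tr], table.features[[test_case, test_ctrl]]
        )
        clf = _fit_svm(x_tr, y, C)
        s = clf.decision_function(x_te)
        scores.extend(s.tolist())
        truth.extend([1, 0])
    scores_arr = np.asarray(scores)
    truth_arr = np.asarray(truth)
    sens = float((scores_arr[truth_arr == 1] > 0).mean() * 100)
    spec = float((scores_arr[truth_arr == 0] <= 0).mean() * 100)
    auc = float(roc_auc_score(truth_arr, scores_arr) * 100)
    return ClassifierReport(
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_iter=n_iter,
        seed=seed,
        extras={"train_per_class": train_per_class, "C": C},
    )


def auc_permutation_p(
    table: FeatureTable,
    observed_auc: float,
    train_per_class: int,
    n_perm: int = 50000,
    cv_iter: int = 200,
    C: float = 1.0,
    seed: int | None = None,
) -> float:
    """Permutation p of an observed AUC against the label-shuffled null.

    Each permutation shuffles the subject labels and reruns the balanced
    LOO cross-validation (with ``cv_iter`` inner iterations) to obtain a
    null AUC; p = (count of null AUCs >= observed + 1) / (n_perm + 1).
    ``n_perm`` and ``cv_iter`` are reducible for desk-scale runs.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p is coarse", RuntimeWarning)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = table.with_labels(rng.permutation(table.labels))
        rep = loo_balanced_cv(
            perm,
            train_per_class,
            n_iter=cv_iter,
            C=C,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if rep.auc >= observed_auc:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def _reconcile(train: FeatureTable, test: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Column intersection by (band, i, j), in training order."""
    test_cols = {key: k for k, key in enumerate(test.feature_index)}
    keep_train, keep_test = [], []
    for k, key in enumerate(train.feature_index):
        if key in test_cols:
            keep_train.append(k)
            keep_test.append(test_cols[key])
    if not keep_train:
        raise ValueError("no common (band, edge) features between train and test tables")
    return train.features[:, keep_train], test.features[:, keep_test]


def transfer_classify(
    train_table: FeatureTable, test_table: FeatureTable, C: float = 1.0
) -> tuple[float, float]:
    """Train on one cohort, score another; report AUC and reversed AUC (%).

    The reversed AUC (100 - AUC) quantifies how well the classifier
    separates the test groups with *opposite* label assignment — above
    50 when the test cohort expresses the training effect with reversed
    sign.
    """
    x_tr_all, x_te_all = _reconcile(train_table, test_table)
    x_tr, x_te = _standardize(x_tr_all, x_te_all)
    y_tr = (train_table.labels == CASE).astype(int)
    y_te = (test_table.labels == CASE).astype(int)
    if len(set(y_tr.tolist())) < 2 or len(set(y_te.tolist())) < 2:
        raise ValueError("both tables must contain both classes")
    clf = _fit_svm(x_tr, y_tr, C)
    auc = float(roc_auc_score(y_te, clf.decision_function(x_te)) * 100)
    return auc, 100.0 - auc
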