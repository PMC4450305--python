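"""Gaussian naive Bayes voxel classifier and subject-level cross-validation.

This is the evaluator behind every feature-selection strategy in the package:
a two-class Gaussian naive Bayes model over the voxel descriptors, scored by
the mean Dice overlap across validation *subjects* in a k-fold split of the
cohort.  Folds always partition subjects, never voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .metrics import ConfusionMatrix, confusion, dice, summarize
from .volume_io import FoldSplit, make_folds

__all__ = [
    "NaiveBayesVoxelClassifier",
    "SubjectScore",
    "CVReport",
    "cross_validate",
    "subject_cv_dice",
]

_LOG_2PI = np.log(2.0 * np.pi)


class NaiveBayesVoxelClassifier(ClassifierMixin, BaseEstimator):
    """Two-class Gaussian naive Bayes with a relative variance floor.

    Class-conditional densities are products of per-feature Gaussians with
    maximum-likelihood means and variances; priors are the training class
    frequencies.  Per-feature variances are floored at ``var_floor_rel``
    times the feature's variance over the whole training set (plus a tiny
    absolute floor), which keeps features that are constant within one class
    from producing degenerate densities.  Posteriors are computed in log
    space.  A voxel is labelled foreground (class A, label 1) when
    P(A | x) >= ``threshold``; the tie at exactly the threshold goes to A.

    Parameters
    ----------
    threshold : float in [0, 1]
        Posterior cut on the foreground class.
    var_floor_rel : float
        Relative variance floor (fraction of each feature's overall variance).
    """

    def __init__(self, threshold: float = 0.5, var_floor_rel: float = 1e-9):
        self.threshold = threshold
        self.var_floor_rel = var_floor_rel

    def fit(self, X, y):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        X, y = check_X_y(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(
                f"need exactly 2 classes in training data, got {classes.tolist()}"
            )
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.classes_ = classes
        self.class_prior_ = counts / counts.sum()
        floor = self.var_floor_rel * X.var(axis=0) + 1e-300
        self.theta_ = np.vstack([X[y == c].mean(axis=0) for c in classes])
        var = np.vstack([X[y == c].var(axis=0) for c in classes])
        self.var_ = np.maximum(var, floor)
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        X = check_array(X, ensure_all_finite=True)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        jll = np.empty((X.shape[0], 2))
        for i in range(2):
            diff = X - self.theta_[i]
            jll[:, i] = (
                np.log(self.class_prior_[i])
                - 0.5 * np.sum(_LOG_2PI + np.log(self.var_[i]) + diff**2 / self.var_[i], axis=1)
            )
        return jll

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities, columns ordered by ``classes_``."""
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def posterior_foreground(self, X) -> np.ndarray:
        """P(class A | x), class A being the larger label (foreground = 1)."""
        return self.predict_proba(X)[:, int(np.argmax(self.classes_))]

    def predict(self, X) -> np.ndarray:
        p_a = self.posterior_foreground(X)
        fg = self.classes_.max()
        bg = self.classes_.min()
        return np.where(p_a >= self.threshold, fg, bg)

    def to_dict(self) -> dict:
        check_is_fitted(self, "theta_")
        return {
            "classes": self.classes_.tolist(),
            "class_prior": self.class_prior_.tolist(),
            "theta": self.theta_.tolist(),
            "var": self.var_.tolist(),
            "threshold": self.threshold,
        }


@dataclass
class SubjectScore:
    """Validation result of one subject in one fold."""

    subject_id: str
    fold: int
    cm: ConfusionMatrix
    dice: float


@dataclass
class CVReport:
    """Per-subject validation scores of a k-fold run plus their aggregates."""

    k: int
    scores: list[SubjectScore] = field(default_factory=list)

    @property
    def dice_values(self) -> np.ndarray:
        return np.array([s.dice for s in self.scores])

    @property
    def mean_dice(self) -> float:
        return float(self.dice_values.mean())

    @property
    def sd_dice(self) -> float:
        return summarize(self.dice_values)[1]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "mean_dice": self.mean_dice,
            "sd_dice": self.sd_dice if len(self.scores) > 1 else None,
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "fold": s.fold,
                    "confusion": s.cm.to_dict(),
                    "dice": s.dice,
                }
                for s in self.scores
            ],
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def cross_validate(
    X,
    y,
    groups,
    folds: FoldSplit | int,
    feature_idx=None,
    classifier: NaiveBayesVoxelClassifier | None = None,
    seed: int = 0,
) -> CVReport:
    """Subject-level k-fold cross-validation of the naive Bayes classifier.

    For each fold the model is fitted on the voxels of all training subjects
    and each validation subject gets its own confusion matrix and Dice score;
    the report aggregates mean +/- sd across validation subjects (every
    subject is validated exactly once).

    ``folds`` may be a precomputed :class:`FoldSplit` or an integer k (a
    seeded split is then drawn here).  ``feature_idx`` restricts the model to
    a column subset.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    groups = np.asarray(groups)
    if feature_idx is not None:
        feature_idx = np.asarray(feature_idx, dtype=int)
        if feature_idx.size == 0:
            raise ValueError("feature subset must be non-empty")
        X = X[:, feature_idx]
    if isinstance(folds, int):
        folds = make_folds(np.unique(groups), folds, seed=seed)
    clf = classifier if classifier is not None else NaiveBayesVoxelClassifier()

    report = CVReport(k=folds.k)
    for f in range(folds.k):
        val_subjects = folds.subjects_in_fold(f)
        val_mask = np.isin(groups, val_subjects)
        X_tr, y_tr = X[~val_mask], y[~val_mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {f}: training data contains a single class")
        model = clf.__class__(**clf.get_params()).fit(X_tr, y_tr)
        for sid in val_subjects:
            sel = groups == sid
            y_hat = model.predict(X[sel])
            cm = confusion(y[sel], y_hat)
            report.scores.append(SubjectScore(subject_id=sid, fold=f, cm=cm, dice=dice(cm)))
    return report


def subject_cv_dice(X, y, groups, folds, feature_idx=None, classifier=None) -> float:
    """Mean per-subject CV Dice — the wrapper-selection criterion."""
    return cross_validate(X, y, groups, folds, feature_idx, classifier).mean_dice
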