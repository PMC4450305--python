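"""Feature-selection strategies for the voxel descriptor.

Four strategies are implemented, one per classical family, plus a PCA
baseline and a random-subset null test:

* filter — two-sample Kolmogorov-Smirnov screening of each feature's class
  distributions (:class:`KSFilter`);
* wrapper — greedy sequential forward selection (:class:`SequentialForwardSelector`)
  and sequential backward elimination (:class:`SequentialBackwardEliminator`),
  both scored by the subject-level cross-validated Dice of the naive Bayes
  classifier;
* embedded — Random Forest impurity importances with a swept acceptance
  threshold (:class:`RandomForestImportanceSelector`);
* :func:`pca_reduce` — principal components retaining a target fraction of
  the variance (a feature *extraction* baseline, not a selection);
* :func:`random_subset_null` — the empirical null distribution of the
  criterion over uniformly drawn feature subsets of a fixed size.

All selectors are scikit-learn-style transformers: ``fit(X, y, groups=...)``
then ``transform(X)``; fitted attributes carry the audit trail (trajectory,
criterion history, p-values).  Ties are always broken towards the lowest
feature index so every run is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .naive_bayes import subject_cv_dice
from .volume_io import FoldSplit, make_folds

__all__ = [
    "SelectionStep",
    "SelectionResult",
    "KSFilter",
    "SequentialForwardSelector",
    "SequentialBackwardEliminator",
    "RandomForestImportanceSelector",
    "ks_filter",
    "sfs",
    "sbe",
    "rf_select",
    "pca_reduce",
    "random_subset_null",
]


@dataclass(frozen=True)
class SelectionStep:
    """One greedy step: the feature moved and the best criterion value there."""

    step: int
    feature: int
    criterion: float
    action: str  # "added" | "removed"


@dataclass
class SelectionResult:
    """Outcome of one selection run: the subset plus its audit trail."""

    method: str
    selected: list[int]
    criterion_history: list[float] = field(default_factory=list)
    trajectory: list[SelectionStep] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected feature indices must be unique")

    def to_dict(self, feature_names=None) -> dict:
        names = None
        if feature_names is not None:
            names = [feature_names[i] for i in self.selected]
        return {
            "method": self.method,
            "selected": [int(i) for i in self.selected],
            "selected_names": names,
            "criterion_history": [float(c) for c in self.criterion_history],
            "trajectory": [
                {
                    "step": s.step,
                    "feature": int(s.feature),
                    "criterion": float(s.criterion),
                    "action": s.action,
                }
                for s in self.trajectory
            ],
            "parameters": self.parameters,
        }

    def to_json(self, path=None, feature_names=None) -> str:
        payload = json.dumps(self.to_dict(feature_names), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def trajectory_table(self) -> str:
        """Delimited table of the greedy path (step, feature, criterion)."""
        lines = ["step\tfeature\taction\tcriterion"]
        for s in self.trajectory:
            lines.append(f"{s.step}\t{s.feature}\t{s.action}\t{s.criterion:.6f}")
        return "\n".join(lines) + "\n"


class _SubsetSelectorBase(TransformerMixin, BaseEstimator):
    """Shared transform/support machinery for index-subset selectors."""

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "selected_")
        if indices:
            return np.asarray(self.selected_, dtype=int)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[list(self.selected_)] = True
        return mask

    def transform(self, X):
        check_is_fitted(self, "selected_")
        X = np.asarray(X)
        return X[:, np.asarray(self.selected_, dtype=int)]

    def _resolve_folds(self, groups, cv, seed) -> FoldSplit:
        if isinstance(cv, FoldSplit):
            return cv
        if groups is None:
            raise ValueError("groups (per-row subject ids) are required for subject-level CV")
        return make_folds(np.unique(np.asarray(groups)), int(cv), seed=seed)


def brute_force_ks_statistic(a, b) -> float:
    """Two-sample K-S statistic by an explicit ECDF sweep over pooled points.

    Reference implementation kept deliberately independent of scipy; used as
    the oracle for :class:`KSFilter` in the test-suite.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pooled = np.concatenate([a, b])
    ecdf_a = np.searchsorted(a, pooled, side="right") / a.size
    ecdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(ecdf_a - ecdf_b).max())


class KSFilter(_SubsetSelectorBase):
    """Univariate filter: keep features whose class distributions differ.

    For each feature the two-sample Kolmogorov-Smirnov statistic between the
    foreground and background voxel distributions is computed with its
    asymptotic p-value; features with p < ``alpha`` are kept, ordered by
    ascending p-value (ties towards the lower feature index).  Being ECDF
    based, the ranking is invariant under strictly monotone feature
    transforms.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, groups=None):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        a = X[y == 1]
        b = X[y == 0]
        if a.shape[0] == 0 or b.shape[0] == 0:
            raise ValueError("both classes must be non-empty")
        p = X.shape[1]
        self.statistic_ = np.empty(p)
        self.pvalues_ = np.empty(p)
        for j in range(p):
            if a[:, j].std() == 0 and b[:, j].std() == 0 and a[0, j] == b[0, j]:
                self.statistic_[j], self.pvalues_[j] = 0.0, 1.0
                continue
            res = ks_2samp(a[:, j], b[:, j], method="asymp")
            self.statistic_[j] = res.statistic
            self.pvalues_[j] = res.pvalue
        keep = np.flatnonzero(self.pvalues_ < self.alpha)
        order = np.lexsort((keep, self.pvalues_[keep]))
        self.selected_ = [int(i) for i in keep[order]]
        self.n_features_in_ = p
        return self

    def ranking(self) -> np.ndarray:
        """All feature indices ordered by ascending p-value."""
        check_is_fitted(self, "pvalues_")
        return np.lexsort((np.arange(self.pvalues_.size), self.pvalues_))

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            method="ks_filter",
            selected=list(self.selected_),
            parameters={"alpha": self.alpha},
        )


class _GreedyWrapperBase(_SubsetSelectorBase):
    """Common machinery of the two greedy wrapper selectors."""

    def _evaluator(self, X, y, groups, folds):
        if self.evaluator is not None:
            return self.evaluator
        return lambda idx: subject_cv_dice(X, y, groups, folds, feature_idx=idx)

    def _pool(self, p) -> list[int]:
        if self.candidate_pool is None:
            return list(range(p))
        pool = [int(i) for i in self.candidate_pool]
        if len(set(pool)) != len(pool) or (pool and (min(pool) < 0 or max(pool) >= p)):
            raise ValueError("candidate_pool must be unique indices within the matrix")
        return pool


class SequentialForwardSelector(_GreedyWrapperBase):
    """Greedy forward wrapper selection scored by subject-CV Dice.

    At each step every remaining candidate is scored jointly with the current
    set and the best one is added (ties to the lowest index).  The fitted
    subset ``selected_`` is the prefix of the greedy path at the peak of the
    criterion history — the number of kept features is decided by the data,
    not fixed in advance.

    Parameters
    ----------
    cv : int or FoldSplit
        Subject-level fold count or a precomputed split.
    max_steps : int or None
        Cap on the number of greedy steps (None = run to the full pool).
    candidate_pool : sequence of int or None
        Restrict the search to a column subset (desk-scale budget).
    evaluator : callable or None
        ``evaluator(index_list) -> criterion``; defaults to naive Bayes
        subject-CV mean Dice.
    """

    def __init__(self, cv=5, max_steps=None, candidate_pool=None, evaluator=None, seed: int = 0):
        self.cv = cv
        self.max_steps = max_steps
        self.candidate_pool = candidate_pool
        self.evaluator = evaluator
        self.seed = seed

    def fit(self, X, y=None, groups=None):
        X = np.asarray(X)
        if X.size == 0:
            raise ValueError("empty feature matrix")
        folds = None
        if self.evaluator is None:
            folds = self._resolve_folds(groups, self.cv, self.seed)
        score = self._evaluator(X, y, groups, folds)
        pool = self._pool(X.shape[1])
        max_steps = len(pool) if self.max_steps is None else min(self.max_steps, len(pool))

        current: list[int] = []
        history: list[float] = []
        trajectory: list[SelectionStep] = []
        remaining = list(pool)
        for step in range(1, max_steps + 1):
            best_j, best_c = None, -np.inf
            for j in remaining:  # ascending index order -> lowest-index ties win
                c = score(current + [j])
                if c > best_c:
                    best_j, best_c = j, c
            current.append(best_j)
            remaining.remove(best_j)
            history.append(best_c)
            trajectory.append(SelectionStep(step, best_j, best_c, "added"))

        peak = int(np.argmax(history))  # first occurrence -> smallest subset
        self.selected_ = current[: peak + 1]
        self.criterion_history_ = history
        self.trajectory_ = trajectory
        self.best_criterion_ = history[peak]
        self.n_features_in_ = X.shape[1]
        return self

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            method="sfs",
            selected=list(self.selected_),
            criterion_history=list(self.criterion_history_),
            trajectory=list(self.trajectory_),
            parameters={"max_steps": self.max_steps, "seed": self.seed},
        )


class SequentialBackwardEliminator(_GreedyWrapperBase):
    """Greedy backward elimination scored by subject-CV Dice.

    Starts from the full candidate pool; at each step the feature whose
    removal gives the best criterion is dropped (ties to the lowest index).
    ``selected_`` is the surviving set at the peak of the criterion history,
    which includes the untouched starting set as step 0.
    """

    def __init__(self, cv=5, min_features: int = 1, candidate_pool=None, evaluator=None, seed: int = 0):
        self.cv = cv
        self.min_features = min_features
        self.candidate_pool = candidate_pool
        self.evaluator = evaluator
        self.seed = seed

    def fit(self, X, y=None, groups=None):
        X = np.asarray(X)
        if X.size == 0:
            raise ValueError("empty feature matrix")
        folds = None
        if self.evaluator is None:
            folds = self._resolve_folds(groups, self.cv, self.seed)
        score = self._evaluator(X, y, groups, folds)
        pool = self._pool(X.shape[1])
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")

        current = list(pool)
        survivors = [list(current)]
        history = [score(current)]  # step 0: full pool
        trajectory: list[SelectionStep] = []
        step = 0
        while len(current) > self.min_features:
            step += 1
            best_j, best_c = None, -np.inf
            for j in current:
                c = score([i for i in current if i != j])
                if c > best_c:
                    best_j, best_c = j, c
            current.remove(best_j)
            survivors.append(list(current))
            history.append(best_c)
            trajectory.append(SelectionStep(step, best_j, best_c, "removed"))

        peak = int(np.argmax(history))  # first occurrence -> larger surviving set
        self.selected_ = survivors[peak]
        self.criterion_history_ = history
        self.trajectory_ = trajectory
        self.best_criterion_ = history[peak]
        self.n_features_in_ = X.shape[1]
        return self

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            method="sbe",
            selected=list(self.selected_),
            criterion_history=list(self.criterion_history_),
            trajectory=list(self.trajectory_),
            parameters={"min_features": self.min_features, "seed": self.seed},
        )


class RandomForestImportanceSelector(_SubsetSelectorBase):
    """Embedded selection by thresholding Random Forest importances.

    A Random Forest is fitted once on the training voxels and features are
    ranked by mean impurity decrease.  The acceptance threshold is swept over
    ``n_thresholds`` quantiles of the importance distribution (always
    including 0, i.e. the full set); each surviving subset is scored by the
    naive Bayes subject-CV Dice and the best one is kept, preferring the
    larger subset on ties.
    """

    def __init__(self, cv=5, n_estimators: int = 100, n_thresholds: int = 10, evaluator=None, seed: int = 0):
        self.cv = cv
        self.n_estimators = n_estimators
        self.n_thresholds = n_thresholds
        self.evaluator = evaluator
        self.seed = seed

    def fit(self, X, y, groups=None):
        X = np.asarray(X)
        y = np.asarray(y)
        folds = None
        if self.evaluator is None:
            folds = self._resolve_folds(groups, self.cv, self.seed)
        score = (
            self.evaluator
            if self.evaluator is not None
            else (lambda idx: subject_cv_dice(X, y, groups, folds, feature_idx=idx))
        )

        rf = RandomForestClassifier(n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1)
        rf.fit(X, y)
        imp = rf.feature_importances_
        if np.all(imp == 0):
            raise ValueError("all feature importances are zero; nothing to rank")
        self.importances_ = imp

        qs = np.linspace(0.0, 1.0, self.n_thresholds, endpoint=False)
        thresholds = np.unique(np.concatenate([[0.0], np.quantile(imp, qs)]))
        best = None
        self.threshold_history_ = []
        for t in thresholds:
            idx = np.flatnonzero(imp >= t)
            if idx.size == 0:
                continue
            c = score(list(idx))
            self.threshold_history_.append((float(t), int(idx.size), float(c)))
            # strict > keeps the earlier (lower threshold, larger subset) on ties
            if best is None or c > best[0]:
                best = (c, t, idx)
        self.best_criterion_, self.threshold_, idx = best
        self.selected_ = [int(i) for i in idx]
        self.n_features_in_ = X.shape[1]
        return self

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            method="rf",
            selected=list(self.selected_),
            criterion_history=[c for _, _, c in self.threshold_history_],
            parameters={
                "n_estimators": self.n_estimators,
                "threshold": float(self.threshold_),
                "seed": self.seed,
            },
        )


def pca_reduce(X, variance_fraction: float | None = None, n_components: int | None = None):
    """Project onto the leading principal components.

    Exactly one of ``variance_fraction`` (keep the smallest number of
    components whose cumulative explained-variance fraction reaches the
    target) or ``n_components`` must be given.  Returns the projected matrix
    and the explained-variance fractions of *all* components (zero-variance
    directions get fraction 0).
    """
    X = np.asarray(X, dtype=float)
    if (variance_fraction is None) == (n_components is None):
        raise ValueError("give exactly one of variance_fraction or n_components")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    fractions = pca.explained_variance_ratio_
    if variance_fraction is not None:
        if not 0.0 < variance_fraction <= 1.0:
            raise ValueError(f"variance_fraction must lie in (0, 1], got {variance_fraction}")
        ncomp = int(np.searchsorted(np.cumsum(fractions), variance_fraction - 1e-12) + 1)
        ncomp = min(ncomp, fractions.size)
    else:
        if not 1 <= n_components <= fractions.size:
            raise ValueError(f"n_components must lie in [1, {fractions.size}]")
        ncomp = int(n_components)
    return scores[:, :ncomp], fractions


def random_subset_null(
    X,
    y,
    groups,
    folds,
    subset_size: int,
    n_draws: int,
    seed: int = 0,
    reference: float | None = None,
    evaluator=None,
):
    """Empirical null of the criterion over random feature subsets.

    Draws ``n_draws`` uniform subsets of ``subset_size`` features without
    replacement, scores each with the naive Bayes subject-CV Dice, and — if a
    ``reference`` value is given — reports the empirical p-value, the
    fraction of draws whose Dice is >= the reference.

    Returns ``(dice_values, p_value)``; ``p_value`` is None without a
    reference.
    """
    X = np.asarray(X)
    p = X.shape[1]
    if not 1 <= subset_size <= p:
        raise ValueError(f"subset_size must lie in [1, {p}], got {subset_size}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if evaluator is None:
        evaluator = lambda idx: subject_cv_dice(X, y, groups, folds, feature_idx=idx)
    rng = np.random.default_rng(seed)
    values = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(p, size=subset_size, replace=False)
        values[i] = evaluator(list(idx))
    p_value = None if reference is None else float(np.mean(values >= reference))
    return values, p_value


# -- thin functional wrappers ------------------------------------------------


def ks_filter(X, y, alpha: float = 0.05) -> SelectionResult:
    return KSFilter(alpha=alpha).fit(X, y).result()


def sfs(X, y, groups, folds, max_steps=None, candidate_pool=None, evaluator=None, seed=0) -> SelectionResult:
    sel = SequentialForwardSelector(
        cv=folds, max_steps=max_steps, candidate_pool=candidate_pool, evaluator=evaluator, seed=seed
    )
    return sel.fit(X, y, groups=groups).result()


def sbe(X, y, groups, folds, min_features=1, candidate_pool=None, evaluator=None, seed=0) -> SelectionResult:
    sel = SequentialBackwardEliminator(
        cv=folds, min_features=min_features, candidate_pool=candidate_pool, evaluator=evaluator, seed=seed
    )
    return sel.fit(X, y, groups=groups).result()


def rf_select(X, y, groups, folds, n_estimators=100, n_thresholds=10, seed=0) -> SelectionResult:
    sel = RandomForestImportanceSelector(
        cv=folds, n_estimators=n_estimators, n_thresholds=n_thresholds, seed=seed
    )
    return sel.fit(X, y, groups=groups).result()
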