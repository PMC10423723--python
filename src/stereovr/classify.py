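"""Nested cross-validated classifier bench.

Outer loop: leave-one-out over participants — the least biased estimate
on a small clinical cohort and the closest mimic of per-patient
diagnosis.  Inner loop: stratified 5-fold grid search (shuffle on, seed
0) over the fixed hyperparameter spaces of four classifiers (linear and
RBF SVM, kNN, random forest).  Median imputation and min-max scaling are
fitted strictly inside each training fold — never on held-out data.

Accuracy on an N-participant cohort moves in steps of 1/N (each held-out
participant is simply right or wrong), so no standard deviation is
reported; confusion matrices carry the per-class error structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import InvalidConfigError, StereoVRError, StratificationError

CLASSIFIER_IDS = ("svm_linear", "svm_rbf", "knn", "rf")
FEATURE_GROUPS = ("stereo", "pupil", "gaze", "all")
INNER_FOLDS = 5
INNER_SEED = 0  # shuffle seed of the stratified inner folds


@dataclass(frozen=True)
class SearchSpace:
    """A classifier id plus its enumerated hyperparameter grid.

    ``grid`` order is the tie-breaking order: the first grid point with
    the best mean inner-fold accuracy wins.
    """

    classifier_id: str
    grid: tuple[dict, ...]
    fixed: dict = field(default_factory=dict)

    @classmethod
    def default(cls, classifier_id: str, rf_n_estimators: int = 300) -> "SearchSpace":
        """The fixed search spaces of the bench.

        svm_linear: C = 2^N, N ∈ [-10, 10].  svm_rbf: C and gamma = 2^N,
        N ∈ [-10, 10].  knn: 3–15 neighbours × {uniform, distance}.
        rf: max_depth ∈ {2,4,6}, min_samples_split ∈ {2,4,6},
        min_samples_leaf ∈ {1,2,4}; 300 trees, sqrt-feature subsampling,
        bootstrap on.
        """
        exps = [2.0**n for n in range(-10, 11)]
        if classifier_id == "svm_linear":
            grid = tuple({"C": c} for c in exps)
            fixed = {}
        elif classifier_id == "svm_rbf":
            grid = tuple({"C": c, "gamma": g} for c in exps for g in exps)
            fixed = {}
        elif classifier_id == "knn":
            grid = tuple(
                {"n_neighbors": k, "weights": w}
                for k in range(3, 16)
                for w in ("uniform", "distance")
            )
            fixed = {}
        elif classifier_id == "rf":
            grid = tuple(
                {"max_depth": d, "min_samples_split": s, "min_samples_leaf": l}
                for d in (2, 4, 6)
                for s in (2, 4, 6)
                for l in (1, 2, 4)
            )
            fixed = {
                "n_estimators": rf_n_estimators,
                "max_features": "sqrt",  # the classic 'auto' heuristic: √n_features per split
                "bootstrap": True,
            }
        else:
            raise InvalidConfigError(f"unknown classifier {classifier_id!r}")
        return cls(classifier_id=classifier_id, grid=grid, fixed=fixed)

    def make_estimator(self, params: dict):
        if self.classifier_id == "svm_linear":
            return SVC(kernel="linear", random_state=0, **params)
        if self.classifier_id == "svm_rbf":
            return SVC(kernel="rbf", random_state=0, **params)
        if self.classifier_id == "knn":
            return KNeighborsClassifier(**params)
        if self.classifier_id == "rf":
            return RandomForestClassifier(random_state=0, **self.fixed, **params)
        raise InvalidConfigError(f"unknown classifier {self.classifier_id!r}")


class FoldTransform:
    """Median imputation + min-max scaling fitted on one training fold."""

    def __init__(self, X_train: np.ndarray):
        with np.errstate(all="ignore"):
            med = np.nanmedian(X_train, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        self.medians_ = med
        Xf = self._impute(X_train)
        self.min_ = Xf.min(axis=0)
        rng = Xf.max(axis=0) - self.min_
        self.zero_range_ = rng == 0
        rng[self.zero_range_] = 1.0
        self.range_ = rng

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        nan = ~np.isfinite(X)
        if np.any(nan):
            X[nan] = np.broadcast_to(self.medians_, X.shape)[nan]
        return X

    def __call__(self, X: np.ndarray) -> np.ndarray:
        """Scale to the training fold's [0, 1]; evaluation values may
        fall outside — no clipping.  Zero-range features map to 0."""
        X = self._impute(np.atleast_2d(X))
        out = (X - self.min_) / self.range_
        out[:, self.zero_range_] = 0.0
        return out


def rescale_features(train: np.ndarray, eval_: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale both blocks with statistics from the training block."""
    tf = FoldTransform(np.atleast_2d(np.asarray(train, dtype=float)))
    return tf(train), tf(eval_)


def inner_cv_select(
    X: np.ndarray,
    y: np.ndarray,
    space: SearchSpace,
    n_folds: int = INNER_FOLDS,
    seed: int = INNER_SEED,
) -> tuple[dict, float]:
    """Stratified k-fold grid search; returns (best params, best score).

    Every grid point is scored by mean fold accuracy; ties break in grid
    enumeration order.  Imputation and scaling are refitted inside every
    inner fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise StratificationError(
            f"cannot form {n_folds} stratified folds from class counts {dict(zip(classes, counts))}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y):
        tf = FoldTransform(X[tr])
        folds.append((tf(X[tr]), y[tr], tf(X[te]), y[te]))

    best_params, best_score = None, -np.inf
    for params in space.grid:
        scores = []
        try:
            for Xtr, ytr, Xte, yte in folds:
                est = space.make_estimator(params)
                est.fit(Xtr, ytr)
                scores.append(float(np.mean(est.predict(Xte) == yte)))
        except ValueError:
            continue  # infeasible for this fold size (e.g. k > n_train)
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    if best_params is None:
        raise StereoVRError("no feasible grid point for this training-set size")
    return best_params, best_score


@dataclass
class LOOCVResult:
    """Outcome of one nested leave-one-out evaluation."""

    accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted, class order as `classes`
    classes: tuple
    chosen_params: list[dict]
    param_frequencies: list[tuple[str, int]]
    predictions: np.ndarray

    def top_params(self, k: int = 3) -> list[tuple[str, int]]:
        return self.param_frequencies[:k]


def outer_loocv(
    X: np.ndarray,
    y: np.ndarray,
    space: SearchSpace,
    n_inner_folds: int = INNER_FOLDS,
    inner_seed: int = INNER_SEED,
) -> LOOCVResult:
    """Nested LOOCV: tune on the rest, predict the held-out participant."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 6:
        raise StereoVRError(f"cohort of {n} too small for nested LOOCV")
    classes = tuple(np.unique(y))
    preds = np.empty(n, dtype=y.dtype)
    chosen: list[dict] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        params, _ = inner_cv_select(X[tr], y[tr], space, n_inner_folds, inner_seed)
        tf = FoldTransform(X[tr])
        est = space.make_estimator(params)
        est.fit(tf(X[tr]), y[tr])
        preds[i] = est.predict(tf(X[i]))[0]
        chosen.append(params)
    acc = float(np.mean(preds == y))
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for yi, pi in zip(y, preds):
        conf[classes.index(yi), classes.index(pi)] += 1
    freq = Counter(_param_key(p) for p in chosen)
    return LOOCVResult(
        accuracy=acc,
        confusion=conf,
        classes=classes,
        chosen_params=chosen,
        param_frequencies=freq.most_common(),
        predictions=preds,
    )


def _param_key(params: dict) -> str:
    return ", ".join(f"{k}={v}" for k, v in params.items())


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    groups: dict[str, str] | None = None,
    top_k: int = 10,
    importance_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> list[tuple[str, str, float]]:
    """Feature-importance ranking aggregated over outer training folds.

    Default importance: random-forest impurity decrease (300 trees,
    seeded), averaged over the leave-one-out training folds so the
    ranking never sees a held-out participant.  The ranking is reported
    only — it is never used to prune the feature set.  Returns
    (name, group_tag, mean importance), best first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if importance_fn is None:

        def importance_fn(Xt: np.ndarray, yt: np.ndarray) -> np.ndarray:
            rf = RandomForestClassifier(n_estimators=300, random_state=seed)
            rf.fit(Xt, yt)
            return rf.feature_importances_

    n = len(y)
    total = np.zeros(X.shape[1])
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        tf = FoldTransform(X[tr])
        total += importance_fn(tf(X[tr]), y[tr])
    mean_imp = total / n
    order = np.argsort(mean_imp)[::-1][:top_k]
    groups = groups or {}
    return [(feature_names[j], groups.get(feature_names[j], "?"), float(mean_imp[j])) for j in order]


def run_bench(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    group_tags: dict[str, str],
    groups: Sequence[str] = FEATURE_GROUPS,
    classifiers: Sequence[str] = CLASSIFIER_IDS,
    seed: int = 0,
    spaces: dict[str, SearchSpace] | None = None,
    rank: bool = True,
) -> dict:
    """Evaluate the classifier × feature-group cross-product.

    Returns a JSON-serializable report: per-cell accuracy, confusion
    matrix and most frequent hyperparameter settings, plus the top-10
    feature ranking over all features and the accuracy granularity 1/N.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    names = list(feature_names)
    spaces = spaces or {}
    report: dict = {
        "n_participants": int(len(y)),
        "accuracy_granularity_pct": 100.0 / len(y),
        "seed": seed,
        "cells": {},
    }
    for group in groups:
        if group == "all":
            cols = list(range(len(names)))
        else:
            cols = [j for j, nme in enumerate(names) if group_tags.get(nme) == group]
        if not cols:
            raise InvalidConfigError(f"feature group {group!r} selects no columns")
        Xg = X[:, cols]
        for clf in classifiers:
            space = spaces.get(clf) or SearchSpace.default(clf)
            res = outer_loocv(Xg, y, space)
            report["cells"][f"{clf}/{group}"] = {
                "classifier": clf,
                "feature_group": group,
                "n_features": len(cols),
                "accuracy": res.accuracy,
                "confusion": res.confusion.tolist(),
                "classes": [str(c) for c in res.classes],
                "top_params": [
                    {"params": k, "count": int(c)} for k, c in res.top_params(3)
                ],
            }
    if rank:
        report["top_features"] = [
            {"name": nme, "group": grp, "importance": imp}
            for nme, grp, imp in rank_features(X, y, names, group_tags, seed=seed)
        ]
    return report
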