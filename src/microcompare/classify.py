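"""Cohort-membership classification: stratified split, repeated CV, ROC/AUC.

This module owns the reproducibility-critical machinery -- the stratified
70:30 split, 10x10 repeated stratified cross-validation and the ROC/AUC
math -- and treats the learner as a pluggable function.  The default
learner is a bagged ensemble of randomized decision trees (a random
forest) from scikit-learn.

The AUC is computed by a threshold sweep with the trapezoid rule and, with
mid-rank handling of tied scores, coincides with the normalized
Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "stratified_split",
    "repeated_cv",
    "roc_auc",
    "ROCResult",
    "random_forest_learner",
    "classify_cohorts",
]


def stratified_split(
    sample_ids, labels, train_frac: float = 0.70, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive train/test split preserving class proportions.

    Per class, floor(train_frac * n_class) samples go to training; the
    leftover slots needed to reach round(train_frac * n_total) are assigned
    to the classes with the largest fractional parts.  Deterministic given
    ``seed``.
    """
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least two classes")
    counts = {c: int((labels == c).sum()) for c in levels}
    if min(counts.values()) < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    base = {c: int(np.floor(train_frac * n)) for c, n in counts.items()}
    target = int(round(train_frac * len(sample_ids)))
    frac = {c: train_frac * counts[c] - base[c] for c in levels}
    for c in sorted(levels, key=lambda c: -frac[c]):
        if sum(base.values()) >= target:
            break
        base[c] += 1
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for c in levels:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        take = base[c]
        if take == 0 or take == idx.size:
            raise ValueError(f"class {c!r} too small to stratify at train_frac={train_frac}")
        train += [sample_ids[i] for i in idx[:take]]
        test += [sample_ids[i] for i in idx[take:]]
    return train, test


def random_forest_learner(n_estimators: int = 200, seed: int = 0):
    """Default learner factory: bagged randomized trees returning P(class 1)."""

    def fit(X: np.ndarray, y: np.ndarray):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(X, y)

        def score(Xnew: np.ndarray) -> np.ndarray:
            return clf.predict_proba(Xnew)[:, list(clf.classes_).index(1)]

        return score

    return fit


def _stratified_folds(y: np.ndarray, folds: int, rng) -> np.ndarray:
    """Fold id per sample; per-fold class proportions within 1 of global."""
    assignment = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    learner=None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold CV; out-of-fold scores pooled per repeat.

    ``learner(X_train, y_train) -> score_fn`` with ``score_fn(X) ->``
    continuous scores for the positive class.  Returns per-repeat AUCs,
    their mean and SD, and a final model refit on the full data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("repeated_cv supports two classes")
    y01 = (y == classes[1]).astype(int)
    if folds > min(np.bincount(y01)):
        raise ValueError("folds exceed the smallest class count")
    if learner is None:
        learner = random_forest_learner(seed=seed)
    aucs = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        fold_of = _stratified_folds(y01, folds, rng)
        oof = np.empty(y01.size)
        for f in range(folds):
            mask = fold_of == f
            try:
                score = learner(X[~mask], y01[~mask])
            except Exception as exc:  # pragma: no cover - surfacing context
                raise RuntimeError(f"learner failed on repeat {rep}, fold {f}") from exc
            oof[mask] = score(X[mask])
        aucs.append(roc_auc(oof, y01).auc)
    final = learner(X, y01)
    return {
        "auc_per_repeat": aucs,
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=1)) if repeats > 1 else 0.0,
        "model": final,
        "classes": list(classes),
    }


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    split: str = ""


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve by threshold sweep; AUC by the trapezoid rule.

    ``labels`` are binary (1 = positive).  Tied scores contribute half,
    making the trapezoid AUC identical to the normalized Mann-Whitney U
    statistic.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = int(y.sum())
    neg = y.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    yy = y[order]
    # collapse ties: cumulative counts at each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(yy)[distinct]
    fp = np.cumsum(1 - yy)[distinct]
    tpr = np.r_[0.0, tp / pos]
    fpr = np.r_[0.0, fp / neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, s[distinct]]
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def auc_u_statistic(scores, labels) -> float:
    """AUC via the Mann-Whitney U identity (independent cross-check)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    r = stats.rankdata(scores)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    u = r[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classify_cohorts(
    table,
    labels: pd.Series,
    train_frac: float = 0.70,
    folds: int = 10,
    repeats: int = 10,
    learner=None,
    seed: int = 0,
) -> dict:
    """End-to-end harness: split, repeated CV on train, final test AUC.

    ``table`` is an AbundanceTable (features x samples); ``labels`` maps
    sample id -> class.  Returns the split, CV summary, and train/test
    ROC results.
    """
    labels = labels.reindex(table.sample_ids)
    train_ids, test_ids = stratified_split(
        table.sample_ids, labels.to_numpy(), train_frac=train_frac, seed=seed
    )
    X = table.values().T
    pos = pd.unique(labels)[1]
    y = (labels == pos).astype(int)
    lookup = {s: i for i, s in enumerate(table.sample_ids)}
    itrain = [lookup[s] for s in train_ids]
    itest = [lookup[s] for s in test_ids]
    if learner is None:
        learner = random_forest_learner(seed=seed)
    cv = repeated_cv(
        X[itrain], y.iloc[itrain].to_numpy(), learner=learner,
        folds=folds, repeats=repeats, seed=seed,
    )
    model = cv["model"]
    train_roc = roc_auc(model(X[itrain]), y.iloc[itrain].to_numpy())
    train_roc.split = "train"
    test_roc = roc_auc(model(X[itest]), y.iloc[itest].to_numpy())
    test_roc.split = "test"
    return {
        "train_ids": train_ids,
        "test_ids": test_ids,
        "cv": cv,
        "train_roc": train_roc,
        "test_roc": test_roc,
        "positive_class": pos,
    }
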