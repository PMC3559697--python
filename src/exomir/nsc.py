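"""Nearest-shrunken-centroid classification and cross-validated
misclassification curves.

Class centroids are standardized against the overall centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/N),

soft-thresholded toward zero by a shrinkage threshold delta,

    d'_ik = sign(d_ik) * max(|d_ik| - delta, 0),

and the shrunken centroids xbar_i + m_k (s_i + s0) d'_ik classify a new
sample by the smallest standardized squared distance minus 2 log(prior).
As delta grows, features drop out (all d'_ik = 0) and the classifier
degenerates to the prior-majority rule; the cross-validated
misclassification curve over a delta grid shows how few features suffice
to separate the clinical groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ShrunkenCentroidClassifier", "NscModel", "nsc_fit",
           "cv_misclassification"]


def _pooled_within_scale(X: np.ndarray, y_codes: np.ndarray,
                         n_classes: int) -> np.ndarray:
    """Pooled within-class standard deviation per feature
    (features in columns)."""
    N, _ = X.shape
    ssw = np.zeros(X.shape[1])
    for k in range(n_classes):
        block = X[y_codes == k]
        ssw += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    return np.sqrt(ssw / (N - n_classes))


class ShrunkenCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-shrunken-centroid classifier (scikit-learn interface).

    Parameters
    ----------
    delta : float
        Shrinkage threshold applied to the standardized centroid
        differences.  0 disables shrinkage.
    s0 : float or "median"
        Fudge constant added to the per-feature pooled scale; "median"
        uses the median of the scales (the customary default).
    priors : "uniform", "empirical", or array-like
        Class priors entering the discriminant as -2 log(prior).  The
        default is uniform (the study's 6/6/8 groups are near-equal).

    Attributes (after fit)
    ----------------------
    classes_, centroid_ (overall), centroids_ (per class, K x p),
    s_, s0_, dik_ (standardized differences), shrunken_dik_,
    shrunken_centroids_, n_features_surviving_.
    """

    def __init__(self, delta: float = 0.0, s0="median", priors="uniform"):
        self.delta = delta
        self.s0 = s0
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_codes, minlength=K)
        if counts.min() < 2:
            raise ValueError("every class needs >= 2 samples")
        N = X.shape[0]
        self.counts_ = counts
        self.centroid_ = X.mean(axis=0)
        self.centroids_ = np.stack([X[y_codes == k].mean(axis=0)
                                    for k in range(K)])
        self.s_ = _pooled_within_scale(X, y_codes, K)
        self.s0_ = float(np.median(self.s_)) if self.s0 == "median" \
            else float(self.s0)
        mk = np.sqrt(1.0 / counts - 1.0 / N)
        denom = mk[:, None] * (self.s_ + self.s0_)[None, :]
        self.dik_ = (self.centroids_ - self.centroid_) / denom
        self.shrunken_dik_ = np.sign(self.dik_) * np.maximum(
            np.abs(self.dik_) - self.delta, 0.0)
        self.shrunken_centroids_ = self.centroid_ + denom * self.shrunken_dik_
        self.n_features_surviving_ = int(
            (np.abs(self.shrunken_dik_).max(axis=0) > 0).sum())
        if isinstance(self.priors, str):
            if self.priors == "uniform":
                self.priors_ = np.full(K, 1.0 / K)
            elif self.priors == "empirical":
                self.priors_ = counts / N
            else:
                raise ValueError(f"unknown priors {self.priors!r}")
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            if len(self.priors_) != K:
                raise ValueError("priors length must equal n_classes")
        self.n_features_in_ = X.shape[1]
        return self

    def discriminant(self, X) -> np.ndarray:
        """Per-class discriminant scores (smaller is better):
        sum_i (x_i - c'_ik)^2 / (s_i + s0)^2 - 2 log prior_k."""
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scale2 = (self.s_ + self.s0_) ** 2
        diff = X[:, None, :] - self.shrunken_centroids_[None, :, :]
        return (diff ** 2 / scale2).sum(axis=2) - 2.0 * np.log(self.priors_)

    def predict(self, X) -> np.ndarray:
        """Assign each sample to the class of minimal discriminant.

        Exact ties (a fully shrunken model with uniform priors makes all
        discriminants equal) resolve to the larger prior, then the larger
        training class, then label order — the prior-majority class.
        """
        disc = self.discriminant(X)
        preds = np.empty(disc.shape[0], dtype=self.classes_.dtype)
        # priority: larger prior first, then larger class, then label order
        priority = np.lexsort((np.arange(len(self.classes_)),
                               -self.counts_, -self.priors_))
        for i, row in enumerate(disc):
            best = row.min()
            tied = np.flatnonzero(row <= best + 1e-12)
            for k in priority:
                if k in tied:
                    preds[i] = self.classes_[k]
                    break
        return preds


@dataclass
class NscModel:
    """Shrunken-centroid family over a threshold grid, plus (optionally)
    the cross-validated misclassification curves."""
    classes_: np.ndarray
    delta_grid: np.ndarray
    overall_centroid: np.ndarray
    class_centroids: np.ndarray
    s: np.ndarray
    s0: float
    shrunken_diffs: list          # per delta: (K, p) array
    n_surviving: np.ndarray       # per delta
    estimators: list              # fitted ShrunkenCentroidClassifier per delta
    cv_curve: pd.DataFrame | None = None


def nsc_fit(m: pd.DataFrame, samples: pd.DataFrame, delta_grid,
            s0="median", priors="uniform") -> NscModel:
    """Fit the shrunken-centroid family on an expression matrix
    (miRNAs x samples) and a sample table with a ``group`` column."""
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    if delta_grid.size == 0 or (delta_grid < 0).any():
        raise ValueError("delta_grid must be nonempty and nonnegative")
    order = [s for s in m.columns]
    y = samples.set_index("sample").loc[order, "group"].to_numpy()
    X = m.to_numpy(dtype=float).T
    estimators = []
    for d in delta_grid:
        est = ShrunkenCentroidClassifier(delta=float(d), s0=s0,
                                         priors=priors).fit(X, y)
        estimators.append(est)
    first = estimators[0]
    return NscModel(
        classes_=first.classes_,
        delta_grid=delta_grid,
        overall_centroid=first.centroid_,
        class_centroids=first.centroids_,
        s=first.s_, s0=first.s0_,
        shrunken_diffs=[e.shrunken_dik_ for e in estimators],
        n_surviving=np.array([e.n_features_surviving_ for e in estimators]),
        estimators=estimators,
    )


def cv_misclassification(m: pd.DataFrame, samples: pd.DataFrame, delta_grid,
                         s0="median", priors="uniform",
                         n_folds: int | None = None) -> pd.DataFrame:
    """Cross-validated misclassification curves over the threshold grid.

    Leave-one-out by default (the natural choice at the study's n = 20);
    pass ``n_folds`` for stratified k-fold instead.  Returns a tidy frame:
    delta, n_surviving (features surviving on the full data), overall rate,
    and one per-class rate column per group.
    """
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    order = [s for s in m.columns]
    y = samples.set_index("sample").loc[order, "group"].to_numpy()
    X = m.to_numpy(dtype=float).T
    N = X.shape[0]
    classes = np.unique(y)
    if n_folds is None:
        folds = [(np.delete(np.arange(N), i), np.array([i]))
                 for i in range(N)]
    else:
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
        folds = list(skf.split(X, y))
    for train, _ in folds:
        present, cnt = np.unique(y[train], return_counts=True)
        if len(present) < len(classes) or cnt.min() < 2:
            raise ValueError("a fold leaves a class empty or singleton")
    full = nsc_fit(m, samples, delta_grid, s0=s0, priors=priors)
    rows = []
    for di, d in enumerate(delta_grid):
        wrong = {c: 0 for c in classes}
        total = {c: 0 for c in classes}
        for train, test in folds:
            est = ShrunkenCentroidClassifier(delta=float(d), s0=s0,
                                             priors=priors)
            est.fit(X[train], y[train])
            pred = est.predict(X[test])
            for yt, yp in zip(y[test], pred):
                total[yt] += 1
                wrong[yt] += int(yt != yp)
        row = {"delta": d, "n_surviving": int(full.n_surviving[di]),
               "rate_overall": sum(wrong.values()) / sum(total.values())}
        for c in classes:
            row[f"rate_{c}"] = wrong[c] / total[c]
        rows.append(row)
    return pd.DataFrame(rows)
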