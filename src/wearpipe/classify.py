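"""Repeated 5-fold cross-validated elastic-net logistic classification.

The user feature matrix (84 summary features per user) is evaluated in a
repeated k-fold layout (default 10 x 5-fold): within each repeat the users
are randomly split into k non-overlapping partitions; per fold, a power
transform (Yeo-Johnson, followed by centering/scaling to zero mean and
unit variance) and an L1-L2 regularized logistic regression (mixing ratio
0.5) are fitted on the training partitions only, and the held-out
partition is scored with the train-fitted transform and model.  All
out-of-fold scores of a repeat are pooled into ONE AUROC and ONE average
precision, giving ``cv_repeats`` values of each.

Nothing fitted ever sees a held-out row: transform parameters, imputation
medians and model coefficients depend only on training rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import PowerTransformer
from sklearn.utils.validation import check_is_fitted

from .params import PipelineParams


def make_partitions(user_ids: Iterable[str], k: int, seed: int = 0,
                    y: pd.Series | None = None, stratified: bool = False) -> pd.Series:
    """Randomly split users into k non-overlapping folds of near-equal size.

    Returns a Series mapping user_id -> fold index in [0, k).  Fold sizes
    differ by at most one.  With ``stratified=True`` the split balances the
    classes of ``y`` across folds.
    """
    users = list(user_ids)
    if len(users) < k:
        raise ValueError(f"cannot split {len(users)} users into {k} folds")
    rng = np.random.default_rng(seed)
    if stratified:
        if y is None:
            raise ValueError("stratified split requires labels")
        order = []
        for cls in sorted(pd.unique(y)):
            members = [u for u in users if y.loc[u] == cls]
            rng.shuffle(members)
            order.extend(members)
        folds = {u: i % k for i, u in enumerate(order)}
    else:
        perm = list(users)
        rng.shuffle(perm)
        folds = {u: i % k for i, u in enumerate(perm)}
    return pd.Series(folds, name="fold").loc[users]


class FlaggedPowerTransformer(BaseEstimator, TransformerMixin):
    """Yeo-Johnson power transform with standardization; constant columns pass through.

    Fitted on training rows only; transformed training columns have zero
    mean and unit variance.  Columns with zero variance in the training
    data cannot be power-transformed and are passed through unchanged,
    their indices recorded in ``zero_variance_cols_``.
    """

    def fit(self, X, y=None) -> "FlaggedPowerTransformer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("power transform requires at least 2 training rows")
        if np.isnan(X).any():
            raise ValueError("power transform input must not contain missing cells")
        sd = X.std(axis=0)
        self.zero_variance_cols_ = np.flatnonzero(sd == 0)
        self.active_cols_ = np.flatnonzero(sd > 0)
        self.n_features_in_ = X.shape[1]
        self.pt_ = PowerTransformer(method="yeo-johnson", standardize=True)
        if self.active_cols_.size:
            self.pt_.fit(X[:, self.active_cols_])
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pt_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"column mismatch: fitted on {self.n_features_in_}, got {X.shape[1]}"
            )
        out = X.copy()
        if X.shape[0] and self.active_cols_.size:
            out[:, self.active_cols_] = self.pt_.transform(X[:, self.active_cols_])
        return out


def fit_elastic_logistic(X, y, l1_ratio: float = 0.5, strength: float = 1.0,
                         seed: int = 0, max_iter: int = 2_000) -> LogisticRegression:
    """Fit an L1-L2 regularized logistic regression (saga solver).

    ``strength`` is the inverse regularization strength ``C``; the penalty
    is fixed relative to the summed data loss (so uniformly duplicating
    every row is equivalent to doubling ``C``, not a no-op).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes in y")
    model = LogisticRegression(
        solver="saga",
        l1_ratio=l1_ratio,
        C=strength,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation.

    Equals the probability that a random positive outscores a random
    negative, with ties credited 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc undefined: both classes required")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def average_precision(scores, labels) -> float:
    """Average precision as the step-sum over descending score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], (labels[order] == 1).astype(float)
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    # one threshold per distinct score: take the last index of each group
    distinct = np.flatnonzero(np.diff(s, append=np.nan))
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


class ElasticNetPhenotypeClassifier(BaseEstimator, ClassifierMixin):
    """Median imputation -> power transform -> elastic-net logistic regression.

    A scikit-learn classifier over the user feature matrix; all fitted
    state (imputation medians, transform parameters, coefficients) depends
    only on the rows passed to :meth:`fit`.
    """

    def __init__(self, l1_ratio: float = 0.5, C: float = 1.0, seed: int = 0,
                 max_iter: int = 2_000):
        self.l1_ratio = l1_ratio
        self.C = C
        self.seed = seed
        self.max_iter = max_iter

    def _impute(self, X: np.ndarray) -> np.ndarray:
        out = X.copy()
        nan_cols = np.flatnonzero(np.isnan(out).any(axis=0))
        for j in nan_cols:
            out[np.isnan(out[:, j]), j] = self.medians_[j]
        return out

    def fit(self, X, y) -> "ElasticNetPhenotypeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need both classes to fit")
        with np.errstate(all="ignore"):
            med = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isnan(med), 0.0, med)
        self.imputed_cols_ = np.flatnonzero(np.isnan(X).any(axis=0))
        Xi = self._impute(X)
        self.transformer_ = FlaggedPowerTransformer().fit(Xi)
        Xt = self.transformer_.transform(Xi)
        self.model_ = fit_elastic_logistic(Xt, y, self.l1_ratio, self.C,
                                           self.seed, self.max_iter)
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xt = self.transformer_.transform(self._impute(np.asarray(X, dtype=float)))
        return self.model_.predict_proba(Xt)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


@dataclass
class CVResult:
    """Outcome of repeated k-fold evaluation: one pooled AUROC/AP per repeat."""

    auroc: list[float]
    average_precision: list[float]
    fold_assignments: list[dict[str, int]]
    scores: pd.DataFrame  # users x repeats, out-of-fold probability of class 1
    coefficients: list[list[list[float]]] = field(repr=False, default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "auroc": self.auroc,
            "average_precision": self.average_precision,
            "mean_auroc": float(np.mean(self.auroc)),
            "mean_average_precision": float(np.mean(self.average_precision)),
            "fold_assignments": self.fold_assignments,
            "scores": {u: list(map(float, row))
                       for u, row in self.scores.iterrows()},
            "coefficients": self.coefficients,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def cross_validate(X: pd.DataFrame, y: pd.Series,
                   params: PipelineParams | None = None,
                   stratified: bool = False) -> CVResult:
    """Repeated k-fold evaluation of the elastic-net classifier.

    For each repeat a fresh random split is drawn from a seed derived from
    ``(params.rng_seed, repeat index)``; every user is scored exactly once
    per repeat by a model that never saw their row, and the pooled scores
    give one AUROC and one average precision per repeat.
    """
    params = params or PipelineParams()
    users = list(X.index)
    y = y.loc[users]
    if pd.isna(y).any():
        raise ValueError("labels must be known for every user in X")
    if np.unique(y).size < 2:
        raise ValueError("need both classes in the cohort")

    aurocs: list[float] = []
    aps: list[float] = []
    assignments: list[dict[str, int]] = []
    coefs: list[list[list[float]]] = []
    scores = pd.DataFrame(index=X.index, columns=range(params.cv_repeats), dtype=float)

    for rep in range(params.cv_repeats):
        rep_seed = np.random.SeedSequence([params.rng_seed, rep]).generate_state(1)[0]
        folds = make_partitions(users, params.cv_folds, seed=int(rep_seed),
                                y=y, stratified=stratified)
        rep_coefs: list[list[float]] = []
        for fold in range(params.cv_folds):
            test_users = folds.index[folds == fold]
            train_users = folds.index[folds != fold]
            y_train = y.loc[train_users]
            if np.unique(y_train).size < 2:
                raise ValueError(
                    f"repeat {rep} fold {fold}: training set single-class "
                    f"(sizes {y_train.value_counts().to_dict()}); "
                    "cohort too small/imbalanced for this fold layout"
                )
            clf = ElasticNetPhenotypeClassifier(
                l1_ratio=params.l1_ratio, C=params.regularization_strength,
                seed=params.rng_seed,
            ).fit(X.loc[train_users], y_train)
            scores.loc[test_users, rep] = clf.predict_proba(X.loc[test_users])[:, 1]
            rep_coefs.append([float(c) for c in clf.coef_.ravel()])
        pooled = scores[rep]
        aurocs.append(auroc(pooled.to_numpy(), y.to_numpy()))
        aps.append(average_precision(pooled.to_numpy(), y.to_numpy()))
        assignments.append({u: int(f) for u, f in folds.items()})
        coefs.append(rep_coefs)

    return CVResult(aurocs, aps, assignments, scores, coefs)
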