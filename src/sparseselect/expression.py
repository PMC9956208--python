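"""High-dimensional feature pipeline: sparsity filters, ranking, 1-NN, PCA.

Mirrors the usual workflow for sparse expression matrices: drop all-zero and
zero-free columns, keep features with a workable zero proportion (5–50% by
default), rank the survivors by AIC difference, and evaluate gene-count
choices with a 1-nearest-neighbor classifier (leave-one-out training error
and k-fold cross-validation) plus PCA cumulative-variance summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted, validate_data

from .gof import CONTINUOUS_CANDIDATES
from .selection import LOGNORMAL_DICHOTOMY, rank_features

__all__ = [
    "FeatureTable",
    "FilterReport",
    "ZeroProportionFilter",
    "filter_features",
    "one_nn_classify",
    "training_error",
    "cv_rank_and_classify",
    "pca_cumvar",
]


@dataclass
class FeatureTable:
    """N x p non-negative matrix with feature names and per-row class labels."""

    values: np.ndarray
    feature_names: list
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (rows = samples)")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels must match the number of rows")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must match the number of columns")

    @property
    def zero_prop(self) -> np.ndarray:
        return np.mean(self.values == 0, axis=0)


@dataclass
class FilterReport:
    """Counts dropped at each (order-dependent) filtering stage."""

    n_total: int
    n_all_zero: int
    n_no_zero: int
    n_out_of_range: int
    n_kept: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _filter_mask(X, min_zero_prop, max_zero_prop):
    zp = np.mean(X == 0, axis=0)
    all_zero = zp == 1.0
    no_zero = (~all_zero) & (zp == 0.0)
    in_range = (~all_zero) & (~no_zero) & (zp >= min_zero_prop) & (zp <= max_zero_prop)
    report = FilterReport(
        n_total=X.shape[1],
        n_all_zero=int(all_zero.sum()),
        n_no_zero=int(no_zero.sum()),
        n_out_of_range=int((~all_zero & ~no_zero & ~in_range).sum()),
        n_kept=int(in_range.sum()),
    )
    return in_range, report


def filter_features(table: FeatureTable, min_zero_prop: float = 0.05,
                    max_zero_prop: float = 0.50):
    """Drop all-zero columns, then zero-free columns, then keep
    zero proportion in [min, max] (closed interval).

    Returns (filtered FeatureTable, FilterReport).
    """
    mask, report = _filter_mask(table.values, min_zero_prop, max_zero_prop)
    if report.n_kept == 0:
        raise ValueError("no feature survives the zero-proportion filters")
    kept = FeatureTable(
        values=table.values[:, mask],
        feature_names=[n for n, m in zip(table.feature_names, mask) if m],
        labels=table.labels,
    )
    return kept, report


class ZeroProportionFilter(SelectorMixin, BaseEstimator):
    """Scikit-learn selector applying the three-stage zero-proportion filter."""

    def __init__(self, min_zero_prop: float = 0.05, max_zero_prop: float = 0.50):
        self.min_zero_prop = min_zero_prop
        self.max_zero_prop = max_zero_prop

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_2d=True, dtype=float)
        mask, report = _filter_mask(X, self.min_zero_prop, self.max_zero_prop)
        if report.n_kept == 0:
            raise ValueError("no feature survives the zero-proportion filters")
        self.support_mask_ = mask
        self.report_ = report
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


def one_nn_classify(train_X, train_y, query_X):
    """Euclidean 1-NN labels; distance ties go to the lowest training index."""
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.asarray(query_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.ndim != 2 or query_X.ndim != 2 or train_X.shape[1] != query_X.shape[1]:
        raise ValueError("train and query matrices must share the feature axis")
    if train_X.shape[0] == 0:
        raise ValueError("need at least one training row")
    d = pairwise_distances(query_X, train_X)
    nearest = np.argmin(d, axis=1)  # argmin returns the first (lowest) index
    return train_y[nearest]


def training_error(X, y, selected_features=None) -> float:
    """Leave-one-out 1-NN error on the selected columns.

    Each sample is predicted from all *other* samples; with the sample itself
    allowed as its own neighbor the 1-NN error would be identically zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if selected_features is not None:
        X = X[:, np.asarray(selected_features)]
    d = pairwise_distances(X, X)
    np.fill_diagonal(d, np.inf)
    nearest = np.argmin(d, axis=1)
    return float(np.mean(y[nearest] != y))


def cv_rank_and_classify(
    table: FeatureTable,
    gene_counts,
    n_folds: int = 5,
    fixed_family=LOGNORMAL_DICHOTOMY,
    candidates=CONTINUOUS_CANDIDATES,
    nsim: int = 100,
    seed=None,
) -> pd.DataFrame:
    """k-fold CV of top-n feature selection + 1-NN classification.

    Rows are split into ``n_folds`` near-equal random blocks (seeded, no
    stratification).  Within each fold the features are ranked on the
    training rows only (by default with the log-normal-hurdle / log-normal
    fixed-family shortcut) and the held-out rows are classified by 1-NN on
    the top-n columns; errors are pooled over all folds per requested count.
    """
    X, y = table.values, table.labels
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError("n_folds must be in [2, N]")
    rng = np.random.default_rng(seed)
    blocks = np.array_split(rng.permutation(n), n_folds)
    errors = {int(c): 0 for c in gene_counts}
    for test_idx in blocks:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_tr = y[train_mask]
        if set(np.unique(y)) - set(np.unique(y_tr)):
            raise ValueError("a class is absent from a training split")
        ranking = rank_features(
            X[train_mask],
            y_tr,
            feature_names=list(range(X.shape[1])),
            candidates=candidates,
            nsim=nsim,
            fixed_family=fixed_family,
            seed=rng,
        )
        ranked_cols = ranking.table["feature"].to_numpy()
        for c in errors:
            cols = np.asarray(ranked_cols[:c], dtype=int)
            pred = one_nn_classify(
                X[np.ix_(train_mask, cols)], y_tr, X[np.ix_(test_idx, cols)]
            )
            errors[c] += int(np.sum(pred != y[test_idx]))
    return pd.DataFrame(
        {
            "n_genes": list(errors),
            "cv_error": [errors[c] / n for c in errors],
        }
    )


def pca_cumvar(X, selected_features=None, n_components=None) -> np.ndarray:
    """Cumulative explained-variance fractions of PCA on centered columns.

    Columns are centered but not scaled.
    """
    X = np.asarray(X, dtype=float)
    if selected_features is not None:
        X = X[:, np.asarray(selected_features)]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 rows and >= 1 selected column")
    if np.allclose(X, X[0], atol=0):
        raise ValueError("constant matrix has no principal components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return np.cumsum(pca.explained_variance_ratio_)
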