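"""Column standardization and class-indicator construction.

All variables — continuous, binary and ordinal alike — are z-scored
(mean subtracted, divided by the sample standard deviation with the
n-1 denominator) so that mixed-type variables enter the map on a common
scale. The three-level frailty label vector is one-hot encoded into the
n x 3 class matrix Y with column order (non-frail, pre-frail, frail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class ZScoreScaler(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with the unbiased (n-1) standard deviation.

    Columns that are constant in the fitted data are mapped to all zeros
    (their recorded scale is 0) with a warning instead of raising, so
    that bootstrap resamples which happen to lose all carriers of a rare
    binary variable still run.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if X.shape[0] < 2:
            raise ValueError(f"need at least 2 rows to standardize, got {X.shape[0]}")
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in input")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        constant = self.scale_ == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant column(s) standardized to zero",
                RuntimeWarning,
                stacklevel=2,
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        safe = np.where(self.scale_ == 0, 1.0, self.scale_)
        Z = (X - self.mean_) / safe
        Z[:, self.scale_ == 0] = 0.0
        return Z

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = np.asarray(Z, dtype=float)
        return Z * self.scale_ + self.mean_


@dataclass
class StandardizedMatrix:
    """A z-scored matrix together with the fit parameters that produced it."""

    Z: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    variable_names: Optional[Sequence[str]] = None


@dataclass
class ClassMatrix:
    """One-hot n x 3 class indicator matrix, columns (non-frail, pre-frail, frail)."""

    Y: np.ndarray
    class_names: tuple = ("non-frail", "pre-frail", "frail")


def standardize(values, variable_names=None) -> StandardizedMatrix:
    """Z-score each column of a raw matrix (n-1 denominator)."""
    scaler = ZScoreScaler().fit(values)
    return StandardizedMatrix(
        Z=scaler.transform(values),
        column_means=scaler.mean_,
        column_sds=scaler.scale_,
        variable_names=variable_names,
    )


def apply_standardization(values, params: StandardizedMatrix) -> np.ndarray:
    """Scale new rows with previously-fitted means/sds (no refit)."""
    scaler = ZScoreScaler()
    scaler.mean_ = np.asarray(params.column_means, dtype=float)
    scaler.scale_ = np.asarray(params.column_sds, dtype=float)
    scaler.n_features_in_ = scaler.mean_.shape[0]
    return scaler.transform(values)


def make_class_matrix(labels) -> ClassMatrix:
    """One-hot encode 1/2/3 frailty labels into the class matrix Y."""
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, (1, 2, 3)).all():
        bad = sorted(set(labels.tolist()) - {1, 2, 3})
        raise ValueError(f"labels must be in {{1,2,3}}, got {bad}")
    Y = np.zeros((labels.shape[0], 3))
    for j, c in enumerate((1, 2, 3)):
        Y[labels == c, j] = 1.0
    return ClassMatrix(Y=Y)
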