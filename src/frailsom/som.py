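"""Supervised Kohonen self-organizing map on a hexagonal grid.

The map is a grid of units, each carrying a weight vector over the p
standardized patient variables plus one "class plane" entry per frailty
class. During training the class indicator row (scaled by
``class_weight``) is appended to each sample, the best matching unit
(BMU) is found by Euclidean distance on the joint vector, and the BMU
and its neighbours move toward the sample:

    w_u ← w_u + α(t) · h_{u,BMU}(t) · ([z | y] − w_u)

with Gaussian neighbourhood h = exp(−d_hex² / (2σ(t)²)) over hexagonal
lattice distance, and learning rate α and radius σ both decaying
exponentially from their initial to final values over the total number
of sample presentations. Sample order is reshuffled every epoch.

Prediction deliberately ignores the class planes: the BMU of a new
sample is found on the feature entries only, and the predicted class is
the argmax of that unit's class-plane weights, so no label information
leaks into prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .hexgrid import HexGrid
from .preprocessing import make_class_matrix


@dataclass
class ComponentPlane:
    """Map-shaped slice of the weight matrix for one variable or class."""

    name: str
    values: np.ndarray  # one value per unit
    vmin: float
    vmax: float
    is_class_plane: bool = False


def _decay(initial: float, final: float, t: int, total: int) -> float:
    """Exponential interpolation from initial to final over total steps."""
    if total <= 1:
        return initial
    return initial * (final / initial) ** (t / (total - 1))


class SupervisedSOM(ClassifierMixin, BaseEstimator):
    """Supervised self-organizing map classifier.

    Parameters
    ----------
    grid_rows, grid_cols : map dimensions (default 8x8: ~64 units for a
        cohort of ~250, about 4 samples per unit).
    epochs : full passes over the training set.
    lr_initial, lr_final : learning-rate schedule endpoints.
    radius_initial : starting neighbourhood radius in hex-lattice units;
        None means half the grid diagonal.
    radius_final : ending neighbourhood radius.
    class_weight : scale applied to the class-indicator columns relative
        to the standardized features in the joint BMU distance. The
        default 3.0 (~sqrt(p/3) for p=28) makes the expected squared
        contribution of the 3-column class block comparable to that of
        the feature block, so supervision actually shapes the map; at
        1.0 the class columns are swamped by the 28 feature columns.
    random_state : seed for weight initialization and epoch shuffling.

    Attributes (after ``fit``)
    --------------------------
    grid_ : the :class:`~frailsom.hexgrid.HexGrid` geometry.
    w_features_ : units x p feature weights.
    w_classes_ : units x n_classes class-plane weights, clipped to
        [0, class_weight] after training.
    classes_ : sorted unique labels seen in ``y``.
    quantization_error_init_, quantization_error_ : mean feature-space
        distance of training samples to their BMUs before and after
        training.
    """

    def __init__(
        self,
        grid_rows: int = 8,
        grid_cols: int = 8,
        epochs: int = 100,
        lr_initial: float = 0.5,
        lr_final: float = 0.01,
        radius_initial: float | None = None,
        radius_final: float = 0.5,
        class_weight: float = 3.0,
        random_state: int | None = None,
    ):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.epochs = epochs
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.radius_initial = radius_initial
        self.radius_final = radius_final
        self.class_weight = class_weight
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y are not row-aligned")
        if X.shape[0] < 1:
            raise ValueError("need at least one training sample")
        if not np.isfinite(X).all():
            raise ValueError("NaN or infinite values in X")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_initial <= 0 or self.lr_final <= 0:
            raise ValueError("learning rates must be positive")
        if self.radius_final <= 0 or (
            self.radius_initial is not None and self.radius_initial <= 0
        ):
            raise ValueError("radii must be positive")

        grid = HexGrid(self.grid_rows, self.grid_cols)
        n, p = X.shape
        if set(np.unique(y)) <= {1, 2, 3}:
            # frailty convention: keep all three class planes even if a
            # class is absent from this (possibly resampled) training set
            self.classes_ = np.array([1, 2, 3])
            Y = make_class_matrix(y).Y
        else:
            self.classes_ = np.unique(y)
            Y = (y[:, None] == self.classes_[None, :]).astype(float)
        Y = Y * self.class_weight

        rng = np.random.default_rng(self.random_state)
        Wf, Wc = self._init_weights(rng, X, grid.n_units, Y.shape[1])
        self.initial_w_features_ = Wf.copy()
        self.initial_w_classes_ = Wc.copy()

        sigma0 = (
            self.radius_initial
            if self.radius_initial is not None
            else 0.5 * np.hypot(self.grid_rows, self.grid_cols)
        )
        D2 = grid.distances**2
        W = np.hstack([Wf, Wc])
        joint = np.hstack([X, Y])
        total = self.epochs * n
        t = 0
        for _ in range(self.epochs):
            for i in rng.permutation(n):
                alpha = _decay(self.lr_initial, self.lr_final, t, total)
                sigma = _decay(sigma0, self.radius_final, t, total)
                diff = joint[i] - W
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                h = np.exp(-D2[bmu] / (2.0 * sigma * sigma))
                W += (alpha * h)[:, None] * diff
                t += 1
        if not np.isfinite(W).all():
            raise RuntimeError(
                f"non-finite weights after training (lr={self.lr_initial})"
            )

        self.grid_ = grid
        self.w_features_ = W[:, :p]
        self.w_classes_ = np.clip(W[:, p:], 0.0, self.class_weight)
        self.n_features_in_ = p
        self.quantization_error_init_ = self._qe(self.initial_w_features_, X)
        self.quantization_error_ = self._qe(self.w_features_, X)
        return self

    @staticmethod
    def _init_weights(rng, X, n_units, n_classes):
        """Random init: features uniform on each variable's empirical
        range (N(0,1) for degenerate range), class planes uniform [0,1]."""
        p = X.shape[1]
        if X.shape[0] > 0:
            lo, hi = X.min(axis=0), X.max(axis=0)
        else:
            lo = hi = np.zeros(p)
        Wf = rng.uniform(size=(n_units, p)) * (hi - lo) + lo
        flat = hi == lo
        if flat.any():
            Wf[:, flat] = rng.normal(size=(n_units, int(flat.sum())))
        Wc = rng.uniform(size=(n_units, n_classes))
        return Wf, Wc

    @staticmethod
    def _qe(Wf, X):
        d = np.linalg.norm(X[:, None, :] - Wf[None, :, :], axis=2)
        return float(d.min(axis=1).mean())

    # -- inference ---------------------------------------------------------

    def bmu(self, sample, class_vector=None, mode: str = "features_only") -> int:
        """Best matching unit of one sample; ties break to the lowest index.

        In ``joint`` mode the (already class_weight-scaled) class vector
        is appended, as during training; ``features_only`` uses only the
        feature entries, as at prediction time.
        """
        check_is_fitted(self, "w_features_")
        sample = np.asarray(sample, dtype=float)
        if mode == "features_only":
            if sample.shape != (self.n_features_in_,):
                raise ValueError(
                    f"expected {self.n_features_in_} features, got {sample.shape}"
                )
            W = self.w_features_
        elif mode == "joint":
            if class_vector is not None:
                sample = np.concatenate([sample, np.asarray(class_vector, float)])
            W = np.hstack([self.w_features_, self.w_classes_])
            if sample.shape != (W.shape[1],):
                raise ValueError(
                    f"expected joint vector of length {W.shape[1]}, got {sample.shape}"
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        diff = sample - W
        return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))

    def predict(self, X):
        """Predict classes from feature-only BMUs (no label leakage).

        The predicted class is the argmax over the BMU's class-plane
        weights; exact ties resolve to the lowest class index.
        """
        check_is_fitted(self, "w_features_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features")
        d = ((X[:, None, :] - self.w_features_[None, :, :]) ** 2).sum(axis=2)
        bmus = d.argmin(axis=1)
        return self.classes_[self.w_classes_[bmus].argmax(axis=1)]

    def predict_detail(self, sample):
        """Predicted class plus BMU index and its class-plane values."""
        b = self.bmu(sample, mode="features_only")
        planes = self.w_classes_[b]
        return self.classes_[int(planes.argmax())], b, planes

    def quantization_error(self, X) -> float:
        """Mean feature-space distance of samples to their BMUs."""
        check_is_fitted(self, "w_features_")
        X = np.asarray(X, dtype=float)
        return self._qe(self.w_features_, X)

    def component_planes(self, variable_names=None) -> list[ComponentPlane]:
        """One plane per feature plus one per class, with display ranges."""
        check_is_fitted(self, "w_features_")
        p = self.n_features_in_
        if variable_names is None:
            variable_names = [f"var_{j}" for j in range(p)]
        if len(variable_names) != p:
            raise ValueError("variable_names length mismatch")
        planes = []
        for j, name in enumerate(variable_names):
            col = self.w_features_[:, j]
            planes.append(ComponentPlane(name, col, float(col.min()), float(col.max())))
        from .scoring import CLASS_NAMES

        for j, cls in enumerate(self.classes_):
            col = self.w_classes_[:, j]
            label = CLASS_NAMES.get(int(cls), str(cls)) if np.isreal(cls) else str(cls)
            planes.append(
                ComponentPlane(
                    f"class_{label}", col, float(col.min()), float(col.max()),
                    is_class_plane=True,
                )
            )
        return planes


def find_bmu(som: SupervisedSOM, sample, mode: str = "features_only") -> int:
    """Module-level wrapper over :meth:`SupervisedSOM.bmu`."""
    return som.bmu(sample, mode=mode)
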