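"""Principal-component exploration of the standardized cohort matrix.

Because the matrix is z-scored first, this is correlation-matrix PCA.
Score plots of PC1 vs PC2, split by frailty class, give the usual first
look at whether the classes separate linearly (in these cohorts they
overlap substantially, motivating the nonlinear map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA


@dataclass
class PcaResult:
    scores: np.ndarray  # n x k
    loadings: np.ndarray  # p x k, orthonormal columns
    explained_variance_fraction: np.ndarray  # length k, non-increasing


def pca(Z, k: int) -> PcaResult:
    """Top-k principal components of an (already centered/standardized) matrix.

    Deterministic up to the fixed sign convention: each loading column is
    flipped so its largest-magnitude entry is positive.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {k}")
    fit = _SKPCA(n_components=k, svd_solver="full").fit(Z)
    loadings = fit.components_.T.copy()
    scores = fit.transform(Z)
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=fit.explained_variance_ratio_.copy(),
    )


def score_plot_data(result: PcaResult, labels) -> dict[int, np.ndarray]:
    """Partition PC1/PC2 scores into per-class point sets for a score plot."""
    labels = np.asarray(labels)
    if labels.shape[0] != result.scores.shape[0]:
        raise ValueError("labels length does not match number of score rows")
    pts = result.scores[:, :2]
    return {c: pts[labels == c] for c in (1, 2, 3)}
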