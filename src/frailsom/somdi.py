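"""SOM discrimination index (SOMDI) and ΔSOMDI variable ranking.

SOMDI scores how closely a variable's component plane tracks the class
plane of a class of interest. Each map unit is first attached to the
class whose class-plane weight is largest there (so the three class
regions partition the map); each unit's feature-weight vector is then
normalized to unit Euclidean length (preserving sign), and the SOMDI of
class c for variable j is the mean normalized weight component j over
the units of class c. Positive scores vary directly with the class
plane, negative scores inversely; larger magnitude means stronger
discrimination.

With three classes the contrast ΔSOMDI compares the class of interest
against the others. The default "mean" contrast subtracts the mean SOMDI
of the other two classes, which makes the three ΔSOMDI values of any
variable sum exactly to zero; a "max" contrast (subtract the larger of
the other two) is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .scoring import CLASS_NAMES
from .som import SupervisedSOM

Contrast = Literal["mean", "max"]


def class_neurons(som: SupervisedSOM, cls: int) -> np.ndarray:
    """Units whose class-plane argmax is ``cls`` (ties to the lowest class).

    This is exactly the map region that predicts ``cls``, so the three
    sets partition the map.
    """
    idx = int(np.flatnonzero(som.classes_ == cls)[0])
    return np.flatnonzero(som.w_classes_.argmax(axis=1) == idx)


def somdi(som: SupervisedSOM, cls: int) -> np.ndarray:
    """SOMDI score vector (one entry per variable) for one class.

    Units with an all-zero feature-weight vector cannot be normalized and
    are excluded with a warning. An empty class-neuron set yields an
    all-NaN vector with a warning (undefined, not silently zero).
    """
    units = class_neurons(som, cls)
    if units.size == 0:
        warnings.warn(
            f"no units assigned to class {cls}; SOMDI undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(som.n_features_in_, np.nan)
    W = som.w_features_[units]
    norms = np.linalg.norm(W, axis=1)
    ok = norms > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-weight unit(s) excluded from SOMDI",
            RuntimeWarning,
            stacklevel=2,
        )
        if not ok.any():
            return np.full(som.n_features_in_, np.nan)
    return (W[ok] / norms[ok, None]).mean(axis=0)


def delta_somdi(somdi_matrix: np.ndarray, cls: int, contrast: Contrast = "mean") -> np.ndarray:
    """Contrast one class's SOMDI row against the other classes.

    ``mean``: SOMDI_c − mean of the other rows (zero-sum across classes).
    ``max``: SOMDI_c − elementwise max of the other rows.
    NaN (undefined) rows propagate NaN.
    """
    S = np.asarray(somdi_matrix, dtype=float)
    if S.shape[0] != 3:
        raise ValueError("expected a 3 x p SOMDI matrix")
    others = [i for i in range(3) if i != cls - 1]
    if contrast == "mean":
        return S[cls - 1] - S[others].mean(axis=0)
    if contrast == "max":
        return S[cls - 1] - S[others].max(axis=0)
    raise ValueError(f"unknown contrast {contrast!r}")


@dataclass
class SOMDITable:
    """Per-class, per-variable SOMDI and ΔSOMDI with unit assignments."""

    somdi: np.ndarray  # 3 x p
    delta: np.ndarray  # 3 x p
    variable_names: list[str]
    class_neuron_sets: dict[int, np.ndarray]
    contrast: Contrast = "mean"

    def rank_table(self, cls: int, top_k: int | None = None) -> pd.DataFrame:
        """Variables of one class ordered by descending ΔSOMDI.

        ``top_k=None`` keeps only variables with ΔSOMDI > 0 (ranked
        tables for the three classes then typically have unequal
        lengths); exact ties order alphabetically by variable name.
        """
        p = len(self.variable_names)
        if top_k is not None and top_k > p:
            warnings.warn(f"top_k={top_k} > {p} variables; clipping", stacklevel=2)
            top_k = p
        d = self.delta[cls - 1]
        order = sorted(range(p), key=lambda j: (-d[j], self.variable_names[j]))
        if top_k is None:
            order = [j for j in order if d[j] > 0]
        else:
            order = order[:top_k]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "class": CLASS_NAMES[cls],
                "variable": [self.variable_names[j] for j in order],
                "somdi": self.somdi[cls - 1, order],
                "delta_somdi": d[order],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: class, rank, variable, somdi, delta_somdi."""
        return pd.concat(
            [self.rank_table(c, top_k=len(self.variable_names)) for c in (1, 2, 3)],
            ignore_index=True,
        )


def compute_somdi_table(
    som: SupervisedSOM, variable_names=None, contrast: Contrast = "mean"
) -> SOMDITable:
    """SOMDI and ΔSOMDI for all three classes of a trained map."""
    if variable_names is None:
        variable_names = [f"var_{j}" for j in range(som.n_features_in_)]
    S = np.vstack([somdi(som, c) for c in (1, 2, 3)])
    D = np.vstack([delta_somdi(S, c, contrast) for c in (1, 2, 3)])
    sets = {c: class_neurons(som, c) for c in (1, 2, 3)}
    return SOMDITable(S, D, list(variable_names), sets, contrast)
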