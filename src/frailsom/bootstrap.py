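"""Bootstrap split protocol and the %PA / %MS / %CC model statistics.

The validation protocol repeats, over a fixed number of iterations
(default 50): select two-thirds of the cohort as a training set, hold
out the rest as a test set, refit standardization on the training rows
only, train a fresh supervised SOM with an iteration-specific seed, and
predict both the training members ("auto prediction") and the held-out
members. Three summary statistics are derived for each of the train and
test sides:

* %CC — percentage correctly classified: the per-iteration fraction of
  correct predictions, averaged over iterations, x100.
* %PA — percentage predictive ability: the per-iteration macro-average
  of per-class correct-classification rates (classes absent from the
  evaluated set are skipped), averaged over iterations, x100. Unlike
  %CC this is insensitive to class imbalance.
* %MS — percentage model stability: for each sample, the fraction of
  its recorded predictions (across the iterations where it appeared on
  the given side) that agree with its modal prediction, averaged over
  samples, x100. A model can be perfectly stable yet wrong.

The default draw takes ceil(2n/3) indices *without* replacement, which
matches the two-thirds / one-third arithmetic exactly; a classical
bootstrap mode (n draws with replacement, out-of-bag test set) is also
provided.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .preprocessing import ZScoreScaler
from .som import SupervisedSOM

Side = Literal["train", "test"]


@dataclass
class SplitPlan:
    """Reproducible per-iteration train/test index sets."""

    n: int
    iterations: int
    seed: Optional[int]
    with_replacement: bool
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]


def make_split_plan(
    n: int,
    iterations: int = 50,
    seed: Optional[int] = None,
    with_replacement: bool = False,
) -> SplitPlan:
    """Draw the two-thirds train / one-third test split plan.

    Without replacement (default): ceil(2n/3) distinct train indices per
    iteration, test = the complement. With replacement: n draws with
    replacement, test = out-of-bag samples.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to split two-thirds/one-third, got {n}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n_train = int(np.ceil(2 * n / 3))
    train, test = [], []
    for _ in range(iterations):
        if with_replacement:
            tr = rng.integers(0, n, size=n)
        else:
            tr = rng.choice(n, size=n_train, replace=False)
        te = np.setdiff1d(np.arange(n), tr)
        train.append(np.sort(tr))
        test.append(te)
    return SplitPlan(n, iterations, seed, with_replacement, train, test)


@dataclass
class BootstrapResult:
    """Recorded per-iteration predictions plus the true labels."""

    plan: SplitPlan
    labels: np.ndarray
    train_predictions: list[np.ndarray] = field(default_factory=list)
    test_predictions: list[np.ndarray] = field(default_factory=list)

    def _iter_sides(self, which: Side):
        if which == "train":
            return zip(self.plan.train_indices, self.train_predictions)
        if which == "test":
            return zip(self.plan.test_indices, self.test_predictions)
        raise ValueError(f"which must be 'train' or 'test', got {which!r}")


def run_bootstrap(
    values_raw: np.ndarray,
    labels: np.ndarray,
    plan: SplitPlan,
    som_params: Optional[dict] = None,
) -> BootstrapResult:
    """Execute the split plan: per iteration refit scaling on the train
    rows, train a fresh SOM with an iteration-derived seed, and record
    predictions for both sides."""
    values_raw = np.asarray(values_raw, dtype=float)
    labels = np.asarray(labels)
    if values_raw.shape[0] != plan.n or labels.shape[0] != plan.n:
        raise ValueError("data/labels rows do not match the split plan")
    som_params = dict(som_params or {})
    base_seed = plan.seed if plan.seed is not None else 0
    result = BootstrapResult(plan, labels)
    for it, (tr, te) in enumerate(zip(plan.train_indices, plan.test_indices)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scaler = ZScoreScaler().fit(values_raw[tr])
                # seed depends on the split content, so identical splits
                # train identically regardless of their position in the plan
                split_hash = zlib.crc32(np.ascontiguousarray(tr, dtype=np.int64).tobytes())
                som_params["random_state"] = (base_seed * 100003 + split_hash) % (2**31 - 1)
                som = SupervisedSOM(**som_params)
                som.fit(scaler.transform(values_raw[tr]), labels[tr])
                result.train_predictions.append(som.predict(scaler.transform(values_raw[tr])))
                result.test_predictions.append(som.predict(scaler.transform(values_raw[te])))
        except Exception as exc:  # noqa: BLE001 - annotate failing iteration
            raise RuntimeError(f"bootstrap iteration {it} failed: {exc}") from exc
    return result


def percent_cc(result: BootstrapResult, which: Side) -> float:
    """Percentage correctly classified, averaged over iterations."""
    rates = []
    for idx, pred in result._iter_sides(which):
        if idx.size:
            rates.append(np.mean(pred == result.labels[idx]))
    return 100.0 * float(np.mean(rates))


def percent_pa(result: BootstrapResult, which: Side) -> float:
    """Percentage predictive ability: iteration-mean of the macro-average
    per-class correct rate (classes absent from an evaluated set skip)."""
    rates = []
    for idx, pred in result._iter_sides(which):
        truth = result.labels[idx]
        per_class = [
            np.mean(pred[truth == c] == c) for c in np.unique(truth)
        ]
        if per_class:
            rates.append(np.mean(per_class))
    return 100.0 * float(np.mean(rates))


def percent_ms(result: BootstrapResult, which: Side) -> float:
    """Percentage model stability: per-sample agreement with the modal
    prediction across iterations, averaged over samples.

    Samples never evaluated on the given side are excluded with a warning.
    """
    n = result.plan.n
    preds_per_sample: list[list] = [[] for _ in range(n)]
    for idx, pred in result._iter_sides(which):
        for i, p in zip(idx, pred):
            preds_per_sample[int(i)].append(p)
    agreements = []
    skipped = 0
    for preds in preds_per_sample:
        if not preds:
            skipped += 1
            continue
        vals, counts = np.unique(preds, return_counts=True)
        agreements.append(counts.max() / len(preds))
    if skipped:
        warnings.warn(
            f"{skipped} sample(s) never evaluated on the {which} side; excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    return 100.0 * float(np.mean(agreements))


def autoprediction_cc(values_raw, labels, som_params: Optional[dict] = None) -> float:
    """%CC of a single model trained and evaluated on the full cohort."""
    values_raw = np.asarray(values_raw, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scaler = ZScoreScaler().fit(values_raw)
        som = SupervisedSOM(**dict(som_params or {}))
        som.fit(scaler.transform(values_raw), labels)
        return 100.0 * float(np.mean(som.predict(scaler.transform(values_raw)) == labels))


def statistics_table(results: dict[str, BootstrapResult]) -> pd.DataFrame:
    """Model-statistics report: one row per instrument, the six columns
    %PA/%MS/%CC x train/test, values rounded to 2 decimals."""
    if not results:
        raise ValueError("need at least one bootstrap result")
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "assessment": name,
                "pa_train": percent_pa(res, "train"),
                "pa_test": percent_pa(res, "test"),
                "ms_train": percent_ms(res, "train"),
                "ms_test": percent_ms(res, "test"),
                "cc_train": percent_cc(res, "train"),
                "cc_test": percent_cc(res, "test"),
            }
        )
    table = pd.DataFrame(rows).set_index("assessment")
    return table.round(2)
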