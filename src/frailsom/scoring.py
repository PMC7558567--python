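"""Frailty instrument scoring: modified Fried Frailty Phenotype and modified FiND.

Two five-item instruments are implemented. The modified Fried Frailty
Phenotype (mFFP) counts positive criteria among weight loss, exhaustion,
low physical activity, slow walking and weak grip; the score bands
0 / 1-2 / 3-5 define the classes non-frail (1), pre-frail (2) and
frail (3). The FiND (Frail Non-Disabled) questionnaire asks five yes/no
questions (A: difficulty walking, B: difficulty climbing, C: weight loss,
D: exhaustion, E: low physical activity); its rule-based categories are
"disabled" if A+B >= 1, "frail" if A+B = 0 and C+D+E >= 1, and "robust"
if all items are negative. The modified FiND (mFiND) additionally maps
the item sum onto the same 0 / 1-2 / 3-5 class bands as the mFFP.

Items are coded yes=1 / no=0 internally so the additive rules hold; the
CSV layer accepts the 1=yes/2=no survey coding and recodes on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

NON_FRAIL, PRE_FRAIL, FRAIL = 1, 2, 3

CLASS_NAMES = {NON_FRAIL: "non-frail", PRE_FRAIL: "pre-frail", FRAIL: "frail"}

MFFP_ITEM_NAMES = (
    "weight_loss",
    "exhaustion",
    "low_physical_activity",
    "slow_walk",
    "weak_grip",
)

FIND_ITEM_NAMES = (
    "A_difficulty_walking",
    "B_difficulty_climbing",
    "C_lost_weight",
    "D_exhaustion",
    "E_low_activity",
)

Instrument = Literal["mffp", "mfind"]


@dataclass(frozen=True)
class FrailtyAssessment:
    """Per-patient scoring outcome under one instrument.

    ``class_label`` uses 1 = non-frail, 2 = pre-frail, 3 = frail.
    ``find_category`` is only populated for the mFiND instrument and holds
    the rule-based FiND category (disabled / frail / robust).
    """

    instrument: Instrument
    score: int
    class_label: int
    find_category: Optional[str] = None

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_label]


def _check_binary_items(items: Sequence[int], n: int = 5) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise ValueError(f"expected {n} items, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"items must be binary 0/1, got {list(arr)}")
    return arr.astype(int)


def classify_score(score: int) -> int:
    """Map a 0-5 item sum onto the three-level frailty class."""
    if score == 0:
        return NON_FRAIL
    if score <= 2:
        return PRE_FRAIL
    return FRAIL


def score_share_fi(frequency_response: int) -> int:
    """Dichotomize the SHARE-FI physical-activity frequency question.

    Responses are coded 1 = "More than once a week", 2 = "Once a week",
    3 = "One to three times a month", 4 = "Hardly ever or never".
    A response of 2 or more flags low physical activity.
    """
    if frequency_response not in (1, 2, 3, 4):
        raise ValueError(
            f"SHARE-FI response must be in 1..4, got {frequency_response!r}"
        )
    return int(frequency_response >= 2)


def score_mffp(items: Sequence[int]) -> FrailtyAssessment:
    """Score the five mFFP items (weight loss, exhaustion, low activity,
    slow walk, weak grip), each 0/1, and band the sum into a class."""
    arr = _check_binary_items(items)
    score = int(arr.sum())
    return FrailtyAssessment("mffp", score, classify_score(score))


def find_category(items: Sequence[int]) -> str:
    """Rule-based FiND category from items A-E coded yes=1/no=0."""
    a, b, c, d, e = _check_binary_items(items)
    if a + b >= 1:
        return "disabled"
    if c + d + e >= 1:
        return "frail"
    return "robust"


def score_mfind(items: Sequence[int]) -> FrailtyAssessment:
    """Score the five FiND items A-E (yes=1/no=0).

    Returns both the rule-based FiND category and the mFiND class band
    (item sum banded 0 / 1-2 / 3-5 as for the mFFP).
    """
    arr = _check_binary_items(items)
    score = int(arr.sum())
    return FrailtyAssessment("mfind", score, classify_score(score), find_category(arr))


def score_cohort(cohort, instrument: Instrument) -> list[FrailtyAssessment]:
    """Score every patient in a cohort under the given instrument."""
    scorer, frame = _instrument_frame(cohort, instrument)
    return [scorer(row) for row in frame.to_numpy()]


def cohort_labels(cohort, instrument: Instrument) -> np.ndarray:
    """Vector of 1/2/3 class labels for a cohort under one instrument.

    This is the label vector used to build the SSOM class matrix.
    """
    scorer, frame = _instrument_frame(cohort, instrument)
    values = frame.to_numpy()
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValueError(f"{instrument} item columns must be binary 0/1")
    scores = values.sum(axis=1).astype(int)
    labels = np.full(len(scores), FRAIL)
    labels[scores == 0] = NON_FRAIL
    labels[(scores >= 1) & (scores <= 2)] = PRE_FRAIL
    return labels


def _instrument_frame(cohort, instrument: Instrument):
    if instrument == "mffp":
        return score_mffp, cohort.mffp_items
    if instrument == "mfind":
        return score_mfind, cohort.mfind_items
    raise ValueError(f"unknown instrument {instrument!r}")
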