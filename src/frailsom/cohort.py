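"""Synthetic elderly cohorts with planted frailty-class structure.

The generator emulates the shape of an outpatient geriatric cohort:
n patients in three frailty classes (non-frail / pre-frail / frail, the
majority non-frail), 28 mixed-type health and socioeconomic variables,
and the per-patient item answers of the two frailty instruments. Each
variable carries a baseline distribution plus per-class effects, so the
classes differ in the designated "discriminative" variables while
overlapping everywhere else.

Variable kinds and their class effects:

* ``binary`` — Bernoulli with baseline prevalence; effects are additive
  prevalence shifts per class (validated to stay in [0, 1]).
* ``ordinal`` — integer levels 1..L from a categorical distribution;
  effects are exponential-tilt slopes applied to the baseline level
  probabilities, ``p_c(l) ∝ p(l) · exp(effect_c · (l − (L+1)/2))``, so a
  positive slope shifts mass toward high levels while probabilities stay
  normalized for any slope.
* ``continuous`` — Gaussian; effects are additive mean shifts.

With ``item_consistency`` on, the five Fried-phenotype items are drawn
so each patient's item count falls in the band of their planted class
(0 / 1-2 / 3-5), making the gold-standard instrument recover the planted
class exactly. The FiND items agree with the planted band only with a
configurable probability, emulating an imperfect screening instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import FIND_ITEM_NAMES, MFFP_ITEM_NAMES

VariableKind = Literal["binary", "ordinal", "continuous"]

#: Default mixture weights over (non-frail, pre-frail, frail).
DEFAULT_CLASS_WEIGHTS = (0.55, 0.30, 0.15)

#: Probability that a patient's FiND item count lands in the band of
#: their planted class (otherwise it falls in an adjacent band).
DEFAULT_FIND_AGREEMENT = 0.78


class ConfigurationError(ValueError):
    """Raised for invalid cohort or variable configuration."""


@dataclass(frozen=True)
class VariableSpec:
    """Distribution of one patient variable, by frailty class.

    ``class_effects`` holds one effect per class (non-frail, pre-frail,
    frail); its meaning depends on ``kind`` (see module docstring).
    """

    name: str
    kind: VariableKind
    baseline: dict
    class_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    levels: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")
        if len(self.class_effects) != 3:
            raise ConfigurationError(f"{self.name}: need 3 class effects")
        if self.kind == "binary":
            p = self.baseline.get("prevalence")
            if p is None:
                raise ConfigurationError(f"{self.name}: binary needs 'prevalence'")
            for c, eff in enumerate(self.class_effects):
                if not 0.0 <= p + eff <= 1.0:
                    raise ConfigurationError(
                        f"{self.name}: class {c + 1} prevalence {p + eff} outside [0, 1]"
                    )
        elif self.kind == "ordinal":
            probs = np.asarray(self.baseline.get("probs", ()), dtype=float)
            if probs.ndim != 1 or probs.size < 2:
                raise ConfigurationError(f"{self.name}: ordinal needs >= 2 level probs")
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                raise ConfigurationError(f"{self.name}: level probs must be a distribution")
            if self.levels is not None and self.levels != probs.size:
                raise ConfigurationError(f"{self.name}: levels != len(probs)")
            object.__setattr__(self, "levels", int(probs.size))
        else:
            sd = self.baseline.get("sd")
            if sd is None or sd <= 0:
                raise ConfigurationError(f"{self.name}: continuous needs sd > 0")
            if "mean" not in self.baseline:
                raise ConfigurationError(f"{self.name}: continuous needs 'mean'")

    def class_distribution(self, cls: int) -> dict:
        """Effective distribution parameters for class ``cls`` in {1,2,3}."""
        eff = self.class_effects[cls - 1]
        if self.kind == "binary":
            return {"prevalence": self.baseline["prevalence"] + eff}
        if self.kind == "continuous":
            return {"mean": self.baseline["mean"] + eff, "sd": self.baseline["sd"]}
        probs = np.asarray(self.baseline["probs"], dtype=float)
        lv = np.arange(1, probs.size + 1)
        tilted = probs * np.exp(eff * (lv - (probs.size + 1) / 2.0))
        return {"probs": tilted / tilted.sum()}

    def class_mean(self, cls: int) -> float:
        """Expected value of the variable within class ``cls``."""
        d = self.class_distribution(cls)
        if self.kind == "binary":
            return d["prevalence"]
        if self.kind == "continuous":
            return d["mean"]
        lv = np.arange(1, len(d["probs"]) + 1)
        return float(lv @ d["probs"])

    def class_sd(self, cls: int) -> float:
        d = self.class_distribution(cls)
        if self.kind == "binary":
            p = d["prevalence"]
            return float(np.sqrt(max(p * (1 - p), 1e-12)))
        if self.kind == "continuous":
            return d["sd"]
        lv = np.arange(1, len(d["probs"]) + 1)
        mu = lv @ d["probs"]
        return float(np.sqrt(max((lv - mu) ** 2 @ d["probs"], 1e-12)))


def planted_frail_effect(spec: VariableSpec) -> float:
    """Standardized frail-class effect: (mean in class 3 minus mean of the
    other classes) divided by the pooled within-class sd. Used to rank how
    strongly a variable was planted in the frail class."""
    m3 = spec.class_mean(3)
    m_other = 0.5 * (spec.class_mean(1) + spec.class_mean(2))
    sd = np.sqrt(np.mean([spec.class_sd(c) ** 2 for c in (1, 2, 3)]))
    return (m3 - m_other) / sd


@dataclass
class CohortTable:
    """Patient-by-variable table plus instrument items and planted classes."""

    data: pd.DataFrame  # n x 28 raw (unstandardized) variable values
    specs: list[VariableSpec]
    true_class: np.ndarray  # planted class in {1,2,3}
    mffp_items: pd.DataFrame  # n x 5 binary, columns MFFP_ITEM_NAMES
    mfind_items: pd.DataFrame  # n x 5 binary (yes=1/no=0), columns FIND_ITEM_NAMES
    seed: Optional[int] = None
    class_weights: tuple = DEFAULT_CLASS_WEIGHTS

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def default_study_specs() -> list[VariableSpec]:
    """The default 28-variable roster with planted class effects.

    Orientation of the effects follows the frailty literature for Thai
    and comparable elderly cohorts: cataract/glaucoma, age and female sex
    carry the strongest frail-class enrichment (cataract/glaucoma the
    largest); stroke, gout, polypharmacy, underlying and other diseases
    are frail/pre-frail enriched; cancer is concentrated in the pre-frail
    class; income, income source, job before retirement, education,
    height and income sufficiency favour the non-frail class. Several
    variables (BMI, heart and kidney disease, smoking, alcohol) carry no
    planted effect and act as noise.
    """
    B, O, C = "binary", "ordinal", "continuous"
    specs = [
        # continuous
        VariableSpec("age", C, {"mean": 68.0, "sd": 6.0}, (0.0, 3.5, 6.5)),
        VariableSpec("height", C, {"mean": 156.0, "sd": 8.0}, (4.0, -1.0, -2.0)),
        VariableSpec("weight", C, {"mean": 58.0, "sd": 10.0}, (1.0, 0.0, -2.0)),
        VariableSpec("bmi", C, {"mean": 23.5, "sd": 3.5}, (0.0, 0.0, 0.0)),
        # binary: demographics and medication
        VariableSpec("sex_female", B, {"prevalence": 0.61}, (-0.08, 0.06, 0.17)),
        VariableSpec("polypharmacy", B, {"prevalence": 0.35}, (-0.15, 0.10, 0.25)),
        VariableSpec("living_alone", B, {"prevalence": 0.10}, (0.0, 0.02, 0.05)),
        VariableSpec("smoking", B, {"prevalence": 0.12}, (0.0, 0.0, 0.0)),
        VariableSpec("alcohol", B, {"prevalence": 0.15}, (0.0, 0.0, 0.0)),
        # binary: diseases
        VariableSpec("cataract_glaucoma", B, {"prevalence": 0.20}, (-0.15, 0.05, 0.50)),
        VariableSpec("stroke", B, {"prevalence": 0.08}, (-0.05, 0.04, 0.17)),
        VariableSpec("gout", B, {"prevalence": 0.10}, (-0.06, 0.05, 0.14)),
        VariableSpec("cancer", B, {"prevalence": 0.06}, (-0.03, 0.06, 0.01)),
        VariableSpec("underlying_diseases", B, {"prevalence": 0.55}, (-0.10, 0.05, 0.20)),
        VariableSpec("other_diseases", B, {"prevalence": 0.30}, (-0.12, 0.05, 0.28)),
        VariableSpec("hypertension", B, {"prevalence": 0.45}, (-0.05, 0.03, 0.10)),
        VariableSpec("diabetes", B, {"prevalence": 0.25}, (-0.04, 0.03, 0.08)),
        VariableSpec("dyslipidemia", B, {"prevalence": 0.40}, (-0.03, 0.02, 0.06)),
        VariableSpec("anemia", B, {"prevalence": 0.12}, (-0.03, 0.02, 0.08)),
        VariableSpec("myalgia", B, {"prevalence": 0.15}, (-0.04, 0.03, 0.08)),
        VariableSpec("dyspepsia", B, {"prevalence": 0.12}, (-0.02, 0.02, 0.05)),
        VariableSpec("heart_disease", B, {"prevalence": 0.10}, (0.0, 0.0, 0.0)),
        VariableSpec("kidney_disease", B, {"prevalence": 0.08}, (0.0, 0.0, 0.0)),
        # ordinal socioeconomic (level 1 = lowest)
        VariableSpec("income", O, {"probs": [0.25, 0.25, 0.20, 0.18, 0.12]},
                     (0.50, -0.10, -0.40)),
        VariableSpec("income_source", O, {"probs": [0.30, 0.25, 0.25, 0.20]},
                     (0.45, -0.10, -0.30)),
        VariableSpec("job_before_retirement", O, {"probs": [0.30, 0.30, 0.25, 0.15]},
                     (0.40, -0.05, -0.25)),
        VariableSpec("education", O, {"probs": [0.35, 0.30, 0.20, 0.15]},
                     (0.45, -0.10, -0.30)),
        VariableSpec("sufficiency_of_income", O, {"probs": [0.30, 0.45, 0.25]},
                     (0.30, -0.20, -0.35)),
    ]
    assert len(specs) == 28
    return specs


_BAND_COUNTS = {1: (0,), 2: (1, 2), 3: (3, 4, 5)}


def _draw_items(rng: np.random.Generator, count: int) -> np.ndarray:
    items = np.zeros(5, dtype=int)
    if count:
        items[rng.choice(5, size=count, replace=False)] = 1
    return items


def generate_cohort(
    n: int,
    seed: Optional[int] = None,
    specs: Optional[Sequence[VariableSpec]] = None,
    class_weights: Sequence[float] = DEFAULT_CLASS_WEIGHTS,
    item_consistency: bool = True,
    find_agreement: float = DEFAULT_FIND_AGREEMENT,
) -> CohortTable:
    """Draw a seeded synthetic cohort from the class-conditional model.

    Parameters
    ----------
    n : number of patients (0 gives an empty table with intact metadata).
    seed : RNG seed; a fixed seed reproduces the cohort bit for bit.
    specs : variable roster; defaults to :func:`default_study_specs`.
    class_weights : mixture weights over (non-frail, pre-frail, frail).
    item_consistency : draw mFFP item counts inside each patient's planted
        class band, so mFFP scoring recovers the planted class exactly.
        When off, items are i.i.d. Bernoulli(0.25), unlinked to class.
    find_agreement : probability that the FiND item count falls in the
        planted band rather than an adjacent one.
    """
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    specs = list(default_study_specs() if specs is None else specs)
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    w = np.asarray(class_weights, dtype=float)
    if w.shape != (3,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ConfigurationError(f"class_weights must be 3 non-negative values summing to 1")
    if not 0.0 <= find_agreement <= 1.0:
        raise ConfigurationError("find_agreement must be in [0, 1]")

    rng = np.random.default_rng(seed)
    true_class = rng.choice((1, 2, 3), size=n, p=w)

    columns = {}
    for spec in specs:
        col = np.empty(n, dtype=float)
        for cls in (1, 2, 3):
            mask = true_class == cls
            m = int(mask.sum())
            d = spec.class_distribution(cls)
            if spec.kind == "binary":
                col[mask] = rng.binomial(1, d["prevalence"], size=m)
            elif spec.kind == "continuous":
                col[mask] = rng.normal(d["mean"], d["sd"], size=m)
            else:
                col[mask] = rng.choice(
                    np.arange(1, len(d["probs"]) + 1), size=m, p=d["probs"]
                )
        columns[spec.name] = col
    data = pd.DataFrame(columns, columns=[s.name for s in specs], dtype=float)

    mffp = np.zeros((n, 5), dtype=int)
    mfind = np.zeros((n, 5), dtype=int)
    for i in range(n):
        cls = int(true_class[i])
        if item_consistency:
            count = int(rng.choice(_BAND_COUNTS[cls]))
        else:
            count = int(rng.binomial(5, 0.25))
        mffp[i] = _draw_items(rng, count)
        band = cls
        if rng.random() >= find_agreement:
            # slip to an adjacent severity band
            if cls == 1:
                band = 2
            elif cls == 3:
                band = 2
            else:
                band = int(rng.choice((1, 3)))
        mfind[i] = _draw_items(rng, int(rng.choice(_BAND_COUNTS[band])))

    return CohortTable(
        data=data,
        specs=specs,
        true_class=true_class,
        mffp_items=pd.DataFrame(mffp, columns=list(MFFP_ITEM_NAMES)),
        mfind_items=pd.DataFrame(mfind, columns=list(FIND_ITEM_NAMES)),
        seed=seed,
        class_weights=tuple(w),
    )
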