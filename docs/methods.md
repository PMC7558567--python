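# Methods

## Frailty instruments

Both instruments take five dichotomized items per patient; upstream
operationalization (e.g. the 4.5 kg weight-loss or 4.5 m walk-time cutoffs,
and the SHARE-FI activity question where a frequency response ≥ 2 flags low
activity) is assumed already applied, as in secondary datasets.

* **mFFP** (modified Fried Frailty Phenotype, the gold standard): items are
  weight loss, exhaustion, low physical activity, slow walking, weak grip.
  The item sum is banded 0 → non-frail (class 1), 1–2 → pre-frail (class 2),
  3–5 → frail (class 3).
* **mFiND** (modified Frail Non-Disabled questionnaire): items A (difficulty
  walking), B (difficulty climbing), C (weight loss), D (exhaustion),
  E (low activity). The rule-based categories are *disabled* if A+B ≥ 1,
  *frail* if A+B = 0 and C+D+E ≥ 1, *robust* otherwise; the modified
  interpretation additionally bands the item sum onto the same three
  classes as the mFFP.

Survey forms commonly code yes = 1 / no = 2; the additive rules above only
hold for yes = 1 / no = 0, so items are recoded on CSV read and the
survey coding is used on disk. Internally everything is 0/1.

## Synthetic cohort generator

The generator emulates a geriatric outpatient cohort: n = 251 by default,
three frailty classes mixed 0.55 / 0.30 / 0.15 (majority non-frail, the
imbalance typical of outpatient samples and a known limitation for
predictive performance), and 28 mixed-type variables — 4 continuous
(age, height, weight, BMI), 19 binary (sex, polypharmacy, disease
indicators) and 5 ordinal socioeconomic variables (income, income source,
job before retirement, education, income sufficiency).

Each variable has a baseline distribution plus per-class effects: additive
prevalence shifts (binary), additive mean shifts (continuous), or
exponential-tilt slopes on the level distribution (ordinal) — tilting
keeps probabilities normalized for any slope, and ordinal levels are
treated numerically downstream since everything is z-scored anyway.
Effect orientation follows the frailty literature: cataract/glaucoma
carries the strongest frail-class enrichment (prevalence 0.05/0.25/0.70
across classes; cataract prevalence above 60% is realistic in frail 75+
populations), followed by age (+6.5 y in the frail class, SD 6) and female
sex (0.53/0.67/0.78, chosen so the mixture-weighted female fraction is
≈ 0.61); stroke, gout, polypharmacy, underlying/other diseases are
frail-enriched, cancer concentrates in the pre-frail class, and income,
income source, pre-retirement job, education, height and income
sufficiency favour the non-frail class. Five variables (BMI, heart and
kidney disease, smoking, alcohol) carry no effect and act as noise.
Magnitudes were fixed once so that the classes overlap substantially in
the first two principal components (no linear separation) while remaining
recoverable by the nonlinear map; the package's tests verify both
properties.

mFFP items are drawn inside the planted class's score band when
`item_consistency` is on, so the gold-standard instrument recovers the
planted class exactly; mFiND item counts agree with the planted band only
with probability 0.78 (otherwise slipping to an adjacent band), emulating
an imperfect screening instrument. Which specific items fire is uniform
given the count.

What the generator does *not* model: missingness (none is assumed),
within-class correlation between variables beyond what the shared class
induces, measurement error in the items, or longitudinal transitions.
Passing recovery tests therefore show the pipeline recovers *this* kind of
planted structure — they say nothing about confounded or missing-data
regimes in real records.

## Preprocessing

All variables are z-scored with the sample (n−1) standard deviation;
binary and ordinal variables are standardized identically to continuous
ones so mixed types share a scale. Columns constant in the fitted data map
to zero with a warning rather than erroring, so bootstrap resamples that
lose all carriers of a rare disease still run. Standardization is refit on
each training subsample and applied to the held-out samples (leakage-safe);
the class label vector is one-hot encoded into the n × 3 class matrix Y
with column order (non-frail, pre-frail, frail).

## PCA exploration

Correlation-matrix PCA (PCA of the z-scored table) provides the initial
linear look; score plots of PC1 vs PC2 by class show overlapping clouds
on default cohorts, motivating the nonlinear map. Component signs are
fixed (largest-magnitude loading entry positive) for determinism.

## Supervised SOM

* **Grid**: planar (non-toroidal) hexagonal lattice, odd-r offset layout,
  default 8×8 — 64 units for n ≈ 250 gives ~4 samples per unit, close to
  the usual ~5√n-units heuristic. Lattice distance uses cube coordinates,
  giving every interior unit exactly 6 neighbours at distance 1.
* **Initialization**: feature weights i.i.d. uniform on each variable's
  empirical range (standard normal for degenerate columns); class planes
  uniform on [0, class_weight]. Fully seeded.
* **Schedule**: 100 epochs of sequential updates; α decays exponentially
  0.5 → 0.01 and σ from half the grid diagonal → 0.5 over the total
  presentations; sample order reshuffled per epoch from the run seed.
* **Supervision**: class indicators are appended to the sample and BMU
  search uses the joint distance during training, features only at
  prediction (argmax of the BMU's class planes, ties to the lowest class).
  The class block is scaled by `class_weight`, default **3.0 ≈ √(p/3)**
  for p = 28: this makes the expected squared contribution of the 3-column
  class block comparable to the 28-column feature block, the same
  rebalancing that XY-fused supervised SOMs apply by weighting the X and Y
  distances equally. With an unscaled class block (weight 1.0) supervision
  contributes ~3/28 of the joint distance and barely shapes the map —
  bootstrap train %CC drops from ~95% to ~83% on default cohorts. The
  weight is a constructor parameter for users who want weaker supervision.
* **Numerics**: class planes are clipped to [0, class_weight] after
  training for interpretability as class evidence (argmax unaffected for
  interior values); BMU ties break to the lowest unit index; NaN inputs
  are rejected up front and non-finite weights abort with a diagnostic;
  with α·h ≤ 1 every weight coordinate is a convex combination of its
  initial value and presented samples, so weights cannot escape the data
  hull. Quantization error (mean feature-space distance of samples to
  their BMUs) is recorded before and after training as a convergence
  diagnostic.

## SOMDI and ΔSOMDI

A unit belongs to the class of its class-plane argmax — exactly the region
that predicts that class — so the three unit sets partition the map. Each
unit's feature-weight vector is normalized to unit Euclidean length
(preserving sign; zero-norm units are excluded with a warning), and
SOMDI(c, j) is the mean normalized component j over class-c units. The
normalization makes scores comparable across units regardless of weight
magnitude; it is the convention of the SOMDI methodology lineage rather
than a uniquely forced choice. ΔSOMDI(c, j) subtracts the mean SOMDI of
the other two classes by default, which gives the exact identity
Σ_c ΔSOMDI(c, j) = 0 used as a test invariant; a max-of-others contrast is
available (`contrast="max"`). Ranked tables truncate at ΔSOMDI > 0 by
default, so per-class tables have unequal lengths; exact ties order
alphabetically. An empty class region yields an explicitly undefined (NaN)
score vector with a warning, never a silent zero.

## Bootstrap validation

50 iterations by default. Each draws ⌈2n/3⌉ training indices *without*
replacement — matching the two-thirds/one-third arithmetic — with the
complement as the test set; `with_replacement=True` gives the classical
bootstrap (n draws, out-of-bag test). Per iteration the scaler is refit on
the training rows and a fresh map is trained with a seed derived from the
master seed and the split content (so identical splits train identically).

* **%CC**: per-iteration fraction correct, averaged over iterations.
* **%PA**: per-iteration macro-average of per-class correct rates
  (classes absent from the evaluated set are skipped), averaged over
  iterations — sensitive to exactly the minority-class weakness that raw
  accuracy hides.
* **%MS**: per-sample fraction of its recorded predictions agreeing with
  its modal prediction, averaged over samples; a model can be perfectly
  stable and wrong, so %MS ≥ %CC is *not* an invariant.

Neither %PA nor %MS has a single canonical definition in the applied
literature; the contracts above were chosen to be symmetric, bounded in
[0, 100] and exactly 100 for a perfect classifier. Train-set statistics
are averaged over the 50 iteration train sets; the full-data
autoprediction %CC is reported separately (`autoprediction_cc`) since
single-model and averaged readings differ.

## Problem sizes and determinism

Default analyses use n = 251, an 8×8 map, 100 epochs and 50 bootstrap
iterations (~30 s on one core). The test suite exercises recovery
properties at 20 seeds × n = 251 and distributional checks at n = 20 000,
chosen to keep three-standard-error bounds tight. Every stochastic step —
cohort draw, weight initialization, epoch shuffling, bootstrap splits —
flows from explicit seeds, and the end-to-end pipeline is byte-identical
under a fixed configuration.

## Known limitations

* The SOMDI normalize-then-average formula and the class-attachment rule
  are one concrete interpretation of a verbally-specified index; the
  contrast mode is switchable but the normalization is fixed.
* Sequential (online) training only — no batch-SOM, growing maps, toroidal
  topology or U-matrix clustering.
* The generator plants marginal class effects only; real cohorts carry
  correlated comorbidities and informative missingness that the recovery
  guarantees do not cover.
* Ranked ΔSOMDI values depend on map geometry and training schedule;
  ranks are far more stable across seeds than raw values, which is why the
  tests assert ranks, not values.
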