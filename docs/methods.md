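# Methods

`pptkit` implements the analysis pipeline of a CGM-monitored dietary
intervention in newly diagnosed type 2 diabetes: a two-period randomized
crossover comparing a personalized postprandial-targeting (PPT) diet with a
Mediterranean-style (MED) diet, followed by a single-arm 6-month PPT phase.
This note records the models, conventions and numerical choices behind each
stage, and what the synthetic cohort generator does and does not emulate.

## Glycemic metrics

All CGM computations treat the trace as a **piecewise-linear curve** between
readings (nominal 15-min sampling) and evaluate integrals and threshold
durations in closed form per segment, interpolating linearly at baseline and
threshold crossings. This makes every metric exactly reproducible by
independent dense-grid integration, which the test suite exploits.

**Meal PPGR (iAUC).** The postprandial glucose response to a logged meal is
the incremental area under the glucose curve in the 2 h after the meal log
time, in mg/dl × h. The baseline is the glucose *at the meal time*,
linearly interpolated between the neighbouring readings of the sensor
connection containing the meal — not a pre-meal minimum, which is the
simplest reading of an "incremental area after the meal" definition. Area
below baseline contributes zero (the common incremental-AUC convention);
a signed "net AUC" is available via `clip_below_baseline=False` for
sensitivity analyses. A meal is gradable only if at least two readings fall
in the window and the covered span reaches 75% of the window
(`min_coverage`, configurable); ungradable meals are flagged with a reason
and counted, never silently dropped.

**Averaged PPGR.** The meal-log-free fluctuation analogue: every sensor
connection is partitioned into consecutive non-overlapping blocks of 9
readings (~2 h at 15-min sampling); each block's iAUC is computed against
its first reading as baseline, and the statistic is the mean over blocks.
A trailing remainder shorter than a block is discarded, and blocks never
span connections. Whether the original windowing was blocked or sliding is
not decidable from the published description; blocked is the default and a
sliding variant (`sliding=True`) is provided.

**Glucose CV** is the sample standard deviation over the mean of all
readings in a period (unitless). **Time above range** is computed per
calendar day (split at local midnight, interpolating the trace at the
crossing): the piecewise-linear curve's duration strictly above each
threshold (140, 150, 160, 170, 180 mg/dl), rescaled from the day's covered
span to a 24-h day so that a fully covered constant day above a threshold
reports 24 h. Classification is strictly greater-than, so a day exactly at
150 mg/dl contributes 0 h above 150. Days with fewer than half of the
expected readings (48 of 96) are excluded to keep sensor-swap days from
biasing daily means. Timestamps are timezone-naive local time throughout,
since all day-level quantities are local "daily" measures.

## Adherence grading

Feedback periods are two weeks. The **composition grade** maps each meal's
predictor score to a grade (1→100, 2→80, 3→50, 4→25, 5→0) and averages
calorie-wise with each meal's energy clamped into the (100, 500) kcal
interval; if under 100 kcal were logged in total (untrimmed — the rule is
about logging volume), no grade is produced. The **calorie grade** is 100
when mean daily intake deviates from the caloric target by at most 15%,
0 from 60% deviation, and linear in the deviation between the knots
(e.g. 50 at 37.5%). Deviation is symmetric, |intake − CT| / CT; the
published description does not sign the deviation, and symmetric is the
conservative reading. The grade is computed on period-mean daily intake.
Reports also list the k best (lowest-score) and worst (highest-score)
meals, ties broken by kcal (ascending for best, descending for worst).

## Menus and meal scores

MED menus are validated by the energy-weighted macronutrient split of the
full candidate pool against the prescribed bounds: carbohydrate 45–65% and
protein 15–20% of energy (inclusive), fat < 35% and saturated fat < 10%
(strict). PPT meal scores rank a meal's predicted PPGR within the person's
reference distribution of predictions; the default cut-points are quintiles
(score 1 = lowest fifth), with ties taking the lower score. The original
scoring thresholds are not publicly recoverable, so the percentile
cut-points are fully configurable and the quintile default is an explicit
assumption. PPT menus are filled with the lowest-score candidates per slot
(ties by lower predicted PPGR, then name), 4–5 options per main slot and
10–12 per snack slot. A dominant food is the single component food strictly
exceeding 70% of meal calories.

## PPGR prediction

Two sklearn-style regressors share an interface. The carbohydrate-counting
baseline is an ordinary least-squares line on carbohydrate grams. The
feature model is a gradient-boosted ensemble of shallow regression trees
(200 trees, depth 3, learning rate 0.05, fixed seed) over meal
macronutrients plus person-level clinical (HbA1c, fasting glucose, weight)
and microbiome features, with negative predictions clipped to zero. It is a
**trainable surrogate** with the same interface and feature classes as
published clinical+microbiome PPGR predictors; no published trained model
or its exact feature list is reproduced. Models are compared by
leave-one-person-out cross-validation: each participant's meals are
predicted by a model trained on everyone else, and explained variance is
reported as 100 × (pooled Pearson r)² of predicted vs measured, matching
the usual predicted-vs-measured scatter presentation; the 1 − SSE/SST
convention is available via `explained_variance("ss")`. A constant
prediction vector has undefined correlation and reports 0.

## Trial statistics

Crossover endpoints are summarized as within-person PPT − MED differences.
The primary model is the paired t test (estimate = mean difference,
dispersion = SD of differences). The rank-based alternative is the Wilcoxon
signed-rank test on the within-person differences — the paired analogue of
the two-sample rank test; a two-sample Mann-Whitney U is not well-defined
on paired differences, so the `mann_whitney` model label runs the
signed-rank test. The sensitivity suite fits linear mixed models with a
participant random intercept and a treatment fixed effect, optionally
adding period and sequence effects, plus a parallel-groups check using
period-1 data only — the canonical crossover model set, labelled as an
assumption since the original sensitivity models are not itemized in the
main text.

Six-month changes use the one-sample t test of (T6 − T0) against zero;
HOMA-IR uses the signed-rank alternative. HOMA-IR is the standard Matthews
mass-unit form, fasting glucose (mg/dl) × fasting insulin (µU/ml) / 405.
Diabetes remission is end HbA1c < 6.5% among participants starting at
≥ 6.5% (boundary values count in the denominator only). The adherence
subgroup comparison splits participants at the median of their mean
feedback grade (ties join the high group) and applies two-sample t tests to
each outcome change; no multiplicity correction is applied across clinical
outcomes, which are reported with unadjusted p-values. Intra- vs
inter-person variability of PPGRs to a shared dominant food compares the
mean within-(person, food) CV against the across-person CV of per-person
median responses, food by food, with a paired t test across foods.

## Microbiome associations

Shannon diversity is reported in nats (−Σ p ln p, 0 ln 0 = 0); the log base
is not specified in the source description and natural log is the package's
choice. The Firmicutes/Bacteroidetes ratio divides summed phylum aggregates
with no pseudocount (a zero Bacteroidetes aggregate yields an absent value
with a warning). The propionate-producer aggregate sums a configurable
taxon set; the shipped default is a literature-derived genus list
(*Akkermansia*, *Bacteroides*, *Prevotella*, *Veillonella*,
*Phascolarctobacterium*, *Dialister*, *Roseburia*) and is explicitly an
assumption, since no canonical membership exists. Change–outcome analysis
correlates raw abundance differences (T6 − baseline; no log-ratio
transform, matching an analysis of raw RA changes) with clinical changes by
Pearson correlation, applies Benjamini–Hochberg adjustment across all
(taxon, outcome) pairs *within each phylogenetic level separately*, and
flags q ≤ 0.15. A per-outcome BH family and a CLR-transformed variant are
available behind flags.

## Synthetic cohort generator

The generator produces complete trial bundles with recorded ground truth:

* **CGM traces**: an AR(1) process (φ = 0.9, stationary SD 5 mg/dl) around
  a person-specific mean (149.7 ± 19 mg/dl between persons, the fasting
  glucose scale of this population) at 15-min sampling, one sensor
  connection per 14-day wear, plus a meal-locked excursion per logged meal.
  The excursion is a log-normal-density-shaped bump (median 0.75 h,
  shape 0.5) scaled so its exact integral over the 2-h window equals the
  meal's generative iAUC — the normalizing mass is the log-normal CDF at
  2 h, so the generative response is available in closed form and the CGM
  metrics are exactly falsifiable by round-trip tests.
* **Meal responses**: generative iAUC = 40 + 1.0 × carbohydrate g +
  person effect (SD 15) + person×food interaction (SD 15) + diet shift
  (−20 mg/dl × h on PPT) + residual (SD 10), truncated at zero. The
  40 mg/dl × h intercept keeps truncation rare so the injected diet effect
  survives to the measured scale.
* **Meal logs**: breakfast/lunch/dinner/snack slots at 07–22 h from a
  10-item food bank with energy-consistent macronutrients; meal scores are
  person-relative quintiles of the expected response per food. Daily energy
  tracks the caloric target (default 2000 kcal/day).
* **Clinical panels**: T0 drawn at this population's baseline scales
  (HbA1c 6.8 ± 0.4%, fasting glucose 149.7 ± 19 mg/dl, ...), T6 = T0 +
  injected effect + noise with the 6-month effect scales of a successful
  intervention (ΔHbA1c −0.39 ± 0.48%, ΔFPG −16.4 ± 24.2 mg/dl, ...), T3
  halfway.
* **Taxa tables**: genus-level Dirichlet compositions (concentration 0.5,
  30 genera, alternating Firmicutes/Bacteroidetes lineages); selected taxa
  receive abundance changes constructed as ρ·z + √(1−ρ²)·ε against a chosen
  standardized clinical change, realized exactly (the other taxa absorb the
  compositional closure), so injected change–change correlations are
  recoverable.
* **Crossover outcomes**: per-period summaries with within-person
  differences N(−20, 16) mg/dl × h — the dispersion scale of the measured
  between-diet PPGR difference — used by the recovery and calibration
  simulations.

What the generator does **not** emulate: physiological glucose–insulin
dynamics (no ODE model, no insulin sensitivity circadian rhythm), sensor
error structure (drift, compression lows, calibration jumps), correlated
food choice and behavioral feedback, missing-at-random vs informative
logging gaps, or realistic phylogenetic correlation among taxa. Passing
tests therefore demonstrate that the analysis code recovers known effects
from data with the right magnitudes and noise topology — not that the
pipeline is robust to every artifact of real CGM or metagenomic data.

## Problem sizes in tests and checks

Simulation-based checks run at the cohort's scale (n = 23 participants,
diet effect −20 mg/dl × h, within-person noise SD 16): effect recovery uses
200 replicates at the outcome level, type-I calibration 1000 null
replicates, FDR calibration 1000 global-null taxa replicates. The full
trace-level end-to-end recovery check runs 100 replicates at 3 days per
period (instead of 14), the package's choice of a desk-sized but
statistically meaningful configuration; effect and noise scales are
unchanged.

## Known limitations

* The MED macronutrient validation applies to the candidate pool of a
  menu, not to realized intake.
* The mixed-model suite assumes a participant random intercept only; with
  two observations per participant, random slopes are not identifiable.
* The intra/inter CV comparison requires at least two participants with at
  least two matched meals per food; sparse foods are skipped and reported.
* BH control is exact under independence or positive dependence of the
  correlation p-values; taxa within a level are compositionally dependent,
  which the per-level FDR treats only approximately (the global-null
  calibration check covers the shipped configuration).
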