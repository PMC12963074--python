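# Methods

## Scoring model

Trabecular attenuation is scored the way clinical densitometry scores areal
BMD. For a patient of sex *s* and age *a* with trabecular HU value *x*:

* **T-score** `T = (x − μ_young(s)) / σ_young(s)`, where μ/σ_young are the
  mean and SD of a young-normal (age ≈ 30) population of the same sex;
* **Z-score** `Z = (x − μ(s, bin(a))) / σ(s, bin(a))` against the age- and
  sex-matched stratum of the reference model. Age strata are 5-year bins
  from 20 to 90 with an open-ended last bin — the conventional densitometry
  stratification. Ages below the first edge yield an undefined Z.

Diagnostic bands: `T > −1.0` → normal, `T < −2.5` → osteoporosis, the closed
interval between → osteopenia. The band edges are tie-broken into
osteopenia so the three half-open bands partition the real line exactly;
both thresholds are arguments of `classify` for sensitivity analyses. An
uncomputable score (missing reference stratum, missing measurement) is not
an error: it propagates as `NaN`/`unknown` through every downstream table,
occupying the `unknown` row/column of transition tables, excluded from
misclassification numerators, retained in subgroup denominators.

The HU statistic driving the scores is the ROI **median** by default
(robust to residual cortical or edge voxels); the mean is selectable
everywhere (`statistic="mean"`).

## ROI geometry

The published description of this kind of pipeline fixes only that the ROI
is built from the left-right and superior-inferior centre of the vertebral
body. The concrete geometry here is deliberately simple and deterministic:
an axis-aligned box centred at the label centroid (all three axes,
including anterior-posterior), spanning a configurable fraction (default
0.5) of the label's bounding extent per axis, intersected with the label
mask, then binary-eroded by a configurable margin (default 1 voxel) to stay
clear of the cortical rim. Properties guaranteed by construction and
verified by tests: ROI ⊆ label; translation equivariance under whole-voxel
shifts; mean/median shift by exactly *c* when the image shifts by *c*.
Median of an even-sized voxel set is the mean of the two central values.
Masks must share the image grid exactly — a mismatch is an error, never a
resample. HU values stay floating point after header rescaling.

Degenerate inputs: an empty label or an ROI that erodes away (e.g. a
one-voxel label) raises a per-vertebra failure that is recorded and skipped;
the remaining levels and the L1–L4 aggregate of the usable vertebrae
continue. Aggregation is **pooled** by default (statistics over the union
of the four ROIs' voxels, voxel counts additive); an unweighted
per-vertebra mean is the alternative mode.

## Phase comparison

All comparisons are within-patient against the non-contrast baseline,
complete pairs only (missing phases are dropped pairwise, never imputed).
Absolute change is `comparison − baseline`; relative change is
`100 · Δ / |baseline|`. The absolute-value denominator is a documented
choice, not an external fact: published relative changes of signed scores
(which can exceed 100 %) come with no stated denominator convention.
Patients with `|baseline| < 1e-9` are excluded from the relative summary
only, with the exclusion count reported. The paired test is the Wilcoxon
signed-rank (`zero_method="wilcox"`); all-tied differences short-circuit to
the degenerate convention p = 1 with an explicit flag.

The **overall change rate** of a reclassification report is the sum of
change events across phase pairs over the subgroup size — with an arterial
and a venous comparison it is the sum of the two pair rates, which is how
the headline ">50 % of patients" figures in this literature are constructed.
Because a patient reclassified in both comparisons counts twice, the
clearly-labelled `unique_patient_change_rate` is reported alongside.
Percentages are kept at full precision internally; display rounding is
half-up at the granularity the field prints (integers for transition
percentages, two decimals for change rates, one decimal for relative HU
changes). No multiple-testing correction is applied; raw p-values are
reported against the conventional 0.05 threshold.

Group tests are thin wrappers over scipy: Mann–Whitney U (two-sided),
Kruskal–Wallis, Pearson chi-squared **without** Yates continuity correction
(so 2×2 tables reproduce the closed-form statistic), Wilcoxon signed-rank.
Tests cross-check each statistic against an independent closed-form or
brute-force computation on random fixtures.

## Synthetic data

The generator emulates the study design the pipeline targets: one cohort,
three phases per patient (non-contrast, arterial, venous), four lumbar
levels plus the pooled aggregate.

Generative model, per patient:

* baseline HU = `μ_young(s) − r · max(0, a − 30) + ε_patient`, with decline
  rate `r = 2 HU/year` and inter-patient spread `ε ~ N(0, 25 HU)`;
  young-normal means 175 (f) / 180 (m) HU, SD 35 HU — values in the range
  reported for lumbar trabecular CT attenuation;
* phase value = baseline + `offset · m_sex · m_age`, with per-patient
  offsets `N(24, 8)` HU arterial and `N(16, 6)` HU venous, a female
  multiplier of 1.4 and an age modifier `1 + 0.03 · max(0, 50 − a)` capped
  at 2 — illustrative settings that reproduce the qualitative pattern of
  stronger enhancement in women and in patients under 50; they are not
  fitted estimates;
* per-vertebra anatomical deviation `N(0, 5)` HU (fixed across phases) plus
  per-measurement noise `N(0, 4)` HU; all HU truncated to the physiologic
  0–500 range. Distributions are normals throughout; the emulated
  literature reports medians/IQRs but no distributional forms.

Demographics default to a vascular-referral-like cohort: n = 597,
female fraction 157/597 (quota-exact), ages 18–95 with a two-piece uniform
targeting a median of 66. The reference population is sampled from the same
age-decline model (5 000 young-normal draws per sex, 500 per age stratum),
so generated cohorts score near Z ≈ 0 against their own reference by
construction.

Phantoms are four elliptic-cylinder vertebral bodies stacked along the
superior-inferior axis (labels 1–4), with a 400 HU cortical shell 1–2
voxels thick, trabecular interior at the patient's phase HU plus optional
voxel noise, and 40 HU soft-tissue background. Label voxel counts match the
analytic ellipse-area × height to within discretisation error.

Determinism: every output is a pure function of (parameters, seed); random
substreams are spawned per patient (`numpy.random.SeedSequence`), so
regenerating one patient's phantom never perturbs another's draws.

**What the generator does not emulate:** CT physics (beam hardening,
scanner spectra, dose), anatomically realistic vertebral shape, fractures
or sclerotic lesions, segmentation failure modes of a real model, and any
real correlation structure between age, sex and enhancement beyond the
monotone modifiers above. Passing tests therefore demonstrate that the
pipeline's arithmetic, bookkeeping and recovery behaviour are correct under
a known generative model — not that a specific clinical cohort's absolute
values would be reproduced. Absolute T-scores on real data depend entirely
on the reference table supplied by the user.

## Worked-example cohort

The reporting stage is additionally exercised on a deterministic cohort
built from explicit category counts (`cohort_from_category_counts`): 597
adults — 157 women, 440 men, 78 under 50 — with non-contrast diagnoses
108 normal / 276 osteopenia / 210 osteoporosis / 3 unknown and the directed
phase-transition counts of a published triphasic reclassification analysis.
Strata are allocated to be exactly consistent with those marginals; the two
venous osteoporosis→normal events in the women-over-50 stratum are an
allocation choice (the source prints only the most common transitions) that
completes the stratum's reported total change rate. This fixture validates
the transition/misclassification arithmetic and display rounding end to
end at negligible cost.

## Problem sizes

Defaults keep everything comfortably interactive: acceptance-level
parameter recovery uses n = 500 patients, direct HU summaries (no
phantoms); the phantom→ROI→scoring closure test uses 10 patients × 3
phases on 40³ grids; brute-force ROI equivalence uses 20 random phantoms up
to 64³; conservation properties use 100 random mini-cohorts. The full
suite runs in a few seconds.

## Known limitations

* The ROI is a box-∩-label heuristic, not a learned trabecular
  segmentation; very thin or irregular labels can erode to a failure.
* Z-scores are undefined below age 20 by the binning choice.
* The relative-change denominator convention for signed scores is a
  package decision (see above); comparisons with sources using another
  convention need re-derivation from absolute changes.
* The event-sum overall change rate can exceed 100 % in principle; use the
  unique-patient rate when a per-patient probability is wanted.
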