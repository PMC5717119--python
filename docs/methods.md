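# Methods

`petprog` implements a prognostic-modelling workflow for oesophageal cancer
built on FDG-PET texture analysis: standardised tumour delineation, a fixed
panel of 16 SUV/texture metrics, and a Cox proportional-hazards prognostic
score with quartile risk stratification and internal validation.  Because no
patient imaging or outcome data are distributed, the package ships a
first-class synthetic-data layer — tumour phantoms and simulated survival
cohorts — on which every stage runs end to end and against which every claim
in the test suite is measured.  This note records the models, the defaults,
and the choices made where the design was genuinely open.

## Segmentation

The metabolic tumour volume (MTV) is delineated inside a bounding box around
the lesion by one of four PET automatic segmentation (PET-AS) methods:

* **threshold_percent_max** — voxels at or above 40% of the box SUVmax;
* **fuzzy_cmeans** — two-cluster fuzzy c-means (fuzzifier m = 2) on voxel
  intensities, centroids initialised at (min, max), foreground = the
  higher-centroid cluster at membership > 0.5;
* **region_grow** — the 26-connected component, above 50% of SUVmax, that
  contains the SUVmax voxel;
* **adaptive_threshold** — iterates `T ← bg + 0.5·(peak − bg)` where `peak`
  is the mean SUV of the hottest region (≥ 90% of SUVmax) and `bg` the mean
  outside the current mask, to a fixed point.  Anchoring on the peak region
  rather than the whole-mask mean prevents the threshold from drifting into
  the background on noisy images.

All masks are reduced to their largest 26-connected component (a single
primary tumour is assumed), and MTV in ml is exactly
`voxel count × spacing product (mm³) / 1000`.

A per-case **method selector** stands in for the trained decision-tree
selection tool used in the source workflow, whose published tree is not
available.  It is retrainable: each training phantom is segmented by every
method, the Dice-best method (ties broken by a fixed precedence:
adaptive_threshold > fuzzy_cmeans > threshold_percent_max > region_grow)
becomes the label, and a depth-3 decision tree is fitted on three case
descriptors — estimated tumour-to-background ratio, approximate volume at
the 40% isocontour, and the intensity coefficient of variation.  Training
cases are importance-weighted by the regret margin (best Dice minus the mean
of the other methods): phantoms on which all methods tie carry no routing
information, while ones where a wrong choice collapses the mask dominate the
fit.  The selector round-trips through a small JSON file.

Two eligibility rules are applied to every segmentation, in order: tumours
with SUVmax < 3 are excluded as poorly FDG-avid, then tumours with
MTV < 5 ml as too small for stable texture analysis.  Both thresholds are
strict (SUVmax = 3.0 and MTV = 5.0 ml are eligible).

## Texture features

Sixteen metrics per case.  SUVmax, SUVmean, MTV and TLG (= SUVmean × MTV,
exactly) plus the histogram shape moments are computed on raw SUVs with the
population divisor N; kurtosis is non-excess (Gaussian → 3, lower bound 1).
All matrix metrics operate on a fixed-bin-width discretisation anchored at
SUV 0 with 0.5-SUV half-open bins (`bin = floor(SUV/0.5) + 1`), which makes
bins comparable across patients on calibrated SUV images and every value
bit-reproducible.  Open conventions are fixed as: entropies in bits (log₂);
one aggregated symmetric grey-level co-occurrence matrix over the 13 unique
3D directions at Chebyshev distance 1, counting only voxel pairs inside the
mask; 26-connectivity for size zones and neighbourhoods; NGTDM coarseness
capped by ε = 1e-6 (a perfectly uniform region scores 10⁶).  Degenerate
cases (constant ROI, no in-mask neighbour pair) are reported as flagged
missing values, never silently dropped.  Every matrix metric is verified in
the tests against naive brute-force enumerators that share no code with the
implementation.

## Survival modelling

The Cox partial likelihood is maximised by Newton's method with step
halving; ties are handled by the Breslow approximation by default (matching
the default of the commercial packages the original analysis used), with
Efron available behind a flag.  Convergence requires a maximum score
component below 1e-8 or a relative log-likelihood change below 1e-9;
standard errors come from the observed information; coefficients beyond
|β| > 20 raise a separation diagnostic.  The fit agrees with lifelines to
~1e-8 on tie-free fixtures and under Efron ties.

Model development mirrors the published procedure: the four long-tailed
metrics (TLG, Histogram Energy, Coarseness, GLCM Homogeneity) enter on the
natural-log scale; events-per-variable is reported (warning below 10);
**backward elimination** removes, at each step, the variable with the
largest exact likelihood-ratio p-value (1 df) above 0.05 until all retained
variables test at or below it.  The "conditional" statistic of the original
software approximates this LR test; the exact test is reproducible and is
used here, with the threshold at the study's significance level (0.05)
rather than the software default of 0.10 (configurable).

The **prognostic score** is the sum of variable × coefficient over the
retained model; the published six-variable weights (stage 0.397, treatment
−1.094, age 0.024, log Histogram Energy −1.320, log TLG 1.748, Histogram
Kurtosis 0.198) are the package defaults.  Patients are split into score
**quartiles by rank**, largest groups first (76/76/75/75 at n = 302,
matching the published group sizes — note that interpolated-percentile
cutoffs would give 76/75/75/76); the reported cutoffs are the closing order
statistic of each lower quartile, and scores tied with a cutoff fall in the
lower group.  Quartile membership is invariant under any monotone transform
of the score, so an overall additive shift (the published quartile score
ranges suggest some undocumented centring) does not affect stratification.
Kaplan-Meier curves, log-log median CIs and the k-sample log-rank test are
delegated to lifelines.  The score × treatment interaction is a 1-df LR
test of `{score, treatment}` vs `{score, treatment, score×treatment}`.
Three nested models — clinical (age, stage, treatment), clinical + SUV
measures, clinical + SUV + texture — are compared by AIC = −2·log L + 2k on
one shared complete-case set, so the likelihoods are comparable.

**Validation** applies a frozen model: development weights and development
quartile cutoffs, no refitting.  Freezing the cutoffs is the defensible
reading of "applying" a developed model to new patients.  Unscorable
patients are flagged and counted, not dropped silently.

## Synthetic data

**Phantoms** are ellipsoidal FDG-avid lesions (tumour mean > background
mean > 0) on a 32³ grid of 4-mm voxels by default, with three optional
corruptions: spatially correlated intra-tumour heterogeneity (white noise
Gaussian-filtered to a stated correlation length, default 8 mm, rescaled to
a stated SD and confined to the tumour), additive white noise, and clipping
at 0.  Suites used for selector training and evaluation are stratified over
four imaging regimes — avid/clean (TBR 4–10), faint/clean (TBR 2–2.6, noise
≤ 0.1 SUV), noisy (noise 0.6–1.1 SUV) and heterogeneous (heterogeneity SD
0.8–1.5 SUV) — because the regimes in which the PET-AS methods fail in
complementary ways are exactly what a method selector exists for; uniform
sampling leaves them too rare to learn.  Methods run inside a snug bounding
box (ground-truth extent + 4 voxels), standing in for the manual box of the
clinical workflow; gross box/lesion imbalance is a known failure mode of
intensity clustering and is not the behaviour under study.

**Cohorts** draw age uniform 39–84, stage-group probabilities
17/56/160/69 out of 302 and curative-treatment probability 158/302 (the
development cohort's marginals).  The 16 metrics come from a two-factor
latent model (a size/avidity factor and a heterogeneity factor) that
induces realistic collinearity — e.g. log MTV, log SUVmean, log TLG and the
size-zone metrics load on the size factor, and TLG = SUVmean × MTV holds
exactly — with marginal scales chosen once as plausible for FDG-avid
oesophageal tumours (e.g. SD(log TLG) ≈ 0.7 from its components,
SD(Histogram Kurtosis) ≈ 1.2 via a shifted lognormal bounded below by 1);
the source study reports no feature distributions, so these are stated
defaults, not estimates of its cohort.  Survival is exponential with rate
`(log 2 / 16) · exp(lp − mean lp)` per month (median OS 16 months at the
centre; centring keeps the event fraction stable across coefficient
choices), with the published six coefficients as the default generating
truth; censoring is exponential at 0.008/month truncated at an
administrative cutoff of 72 months, giving roughly 70–75% events.  Every
generator output is a pure function of its configuration and seed.

What the synthetic layer does **not** emulate: scanner physics (Poisson
sinogram noise, reconstruction artefacts, partial-volume blur), respiratory
motion, non-ellipsoidal tumour shapes, multi-lesion disease, and the true
joint distribution of texture metrics in any real cohort.  Passing tests
therefore demonstrate that the algorithms are implemented correctly and
that the statistical machinery is calibrated — not that the published
cohort-specific results (median OS values, the printed chi-squares or AIC
values, the quartile score ranges) are recovered; those require the
undistributed patient data and are out of scope.

## Problem sizes and numerical choices

The bundled demonstration pipeline uses 30 training + 8 evaluation phantoms
and the study's cohort sizes (302 development / 101 validation); the
selector study uses 120 training / 50 held-out phantoms; Monte-Carlo rates
use 200 replicates (backward-elimination retention), 500 (interaction-test
calibration) and 100 (AIC ordering) at n = 302 or n = 150 — sizes at which
each study's Monte-Carlo error is small relative to the property being
checked while a full run stays in the minutes range on one CPU.  A single
global seed fans out to per-stage seeds by stable CRC hashing of the stage
name, so any stage reruns in isolation byte-identically; reruns of the
whole pipeline with one seed are byte-identical including plots.

Known limitations: the selector's three case descriptors are a stated
stand-in for the (unpublished) feature set of the original selection tool;
DICOM ingestion, SUV computation from raw activity, image registration,
proportional-hazards diagnostics, competing risks and external validation
are out of scope.
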