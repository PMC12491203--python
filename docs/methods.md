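# Methods

`gaitfusion` quantifies lower-limb gait in three clinical groups — healthy
adults, patients with severe knee osteoarthritis (KOA), and patients within
months of total knee arthroplasty (TKA) — along two complementary axes:
*dynamic inter-joint coordination*, measured by morphological features of
the hip–knee cyclogram, and *movement complexity*, measured by the sample
entropy of joint-angle sequences. The two feature families are fused into
one subject-level feature vector, screened statistically, and evaluated
with standard classifiers under nested cross-validation.

## Pipeline

For each subject trial (hip, knee, ankle sagittal flexion angles, degrees,
uniformly sampled; flexion positive, ankle dorsiflexion positive):

1. **Event detection.** Toe-off is the maximum plantarflexion angle — the
   most-negative local extremum of the ankle trace, found with a prominence
   floor of 0.4 × trace RoM and a minimum separation of half the median
   inter-trough interval (two-pass peak search). Heel strike is the
   *initiation point of ankle-angle change* after swing, operationalized as
   the first +→− zero-crossing of the smoothed first difference after each
   trough — equivalently the first local maximum (end-swing dorsiflexion
   peak) — subject to a prominence floor of `onset_prominence_frac`
   (default 0.05) × RoM so noise wiggles on the flat swing plateau are
   ignored. The qualitative event description admits no unique numeric
   rule; this one is explicit, configurable, and validated against
   generator ground truth (≤ 2 samples at 100 Hz). A moving average
   (width 5) is applied *only* inside event detection; exported angles are
   never smoothed or filtered.
2. **Segmentation and normalization.** Cycles run heel strike to next heel
   strike and must contain exactly one toe-off (violations skip the cycle
   with a warning). Each joint's segment is resampled to `n_cycle_points`
   (default 101, the 0–100% biomechanics convention) by a not-a-knot
   interpolating cubic spline. Not-a-knot ends reproduce cubic polynomials
   exactly and avoid the end flattening of natural splines; evaluation is
   strictly interpolation. 3–5 cycles per subject are retained uniformly
   at random (seeded).
3. **Cyclogram morphology.** The hip–knee angle-angle loop (hip on X,
   knee on Y, clockwise for physiological gait) yields: hip/knee range of
   motion (max − min, deg), centroid (mean hip and knee angle, deg),
   perimeter (sum of adjacent point distances plus the closing segment,
   deg) and area (absolute shoelace sum, deg²). Perimeter and area are
   decomposed into stance/swing parts:
   - *perimeter*: each edge belongs to the phase of its starting point,
     the closing edge to swing — partial sums, so stance + swing = total
     exactly;
   - *area*: the loop is split at the toe-off point and each sub-path is
     closed by the shared heel-strike–toe-off chord. The chord's shoelace
     terms cancel, so the signed sub-areas add to the signed total
     exactly, and both are positive for simple physiological loops. Raw
     partial shoelace sums were rejected for the area because they depend
     on the coordinate origin and produce negative stance areas on clean
     gait loops.
   Per-subject features are the mean over the selected cycles (median
   available via `aggregate`).
4. **Sample entropy.** SampEn(m, r, N) = −ln(A/B) with Chebyshev template
   distance, self-matches excluded, and both counts over the N − m
   templates that admit an (m+1)-extension. Defaults m = 2,
   r = 0.1 × SD of the analyzed series (absolute-degrees mode available);
   SD-relative tolerance adapts to the signal's dynamic range and makes
   the measure scale-invariant. Per joint, entropy is computed once on the
   subject's selected cycles concatenated in time order (≈ 300–500
   samples); a per-cycle-mean mode exists. Degenerate cases: zero-variance
   series → 0 with a warning; no matches at either template length → +inf
   with a warning naming the reason.
5. **Group statistics.** Per feature: Shapiro–Wilk per group; Kruskal–
   Wallis omnibus across the three groups; if significant at α = 0.05, all
   three pairwise Mann–Whitney U tests judged at the fixed Bonferroni
   threshold p < 0.017 (0.05/3, applied as a threshold, not as adjusted
   p-values). Categorical variables use a Fisher exact test (Monte-Carlo,
   margins-conditioned via Patefield sampling for tables larger than 2×2 —
   the same scheme R uses — exact for 2×2). ANCOVA fits
   `feature ~ group + age + sex + bmi` by OLS and reports the group main
   effect's F, p and partial η² = SS_group/(SS_group + SS_residual) with
   Type-II sums of squares (Types I/III configurable); Tukey HSD follows
   significant main effects. A side-adjusted variant adds the
   affected/operated-side category, dummy-coded, merging singleton
   categories into the largest so the design stays full rank.
6. **Classification.** Four feature sets — fused (10 cyclogram + 3 entropy
   = 13), cyclogram, entropy, spatiotemporal (speed, stride length, stride
   width, left/right step length) — × four models (RF, RBF-SVM, DT, KNN).
   Outer 5-fold stratified CV; per outer fold, median imputation, Z-score
   standardization and top-10 ANOVA-F selection are fitted on the training
   fold only (leakage is probe-tested), then a 3-fold inner search tunes
   hyperparameters: RF trees 50–100 and depth 3–5 (random search, 20
   draws — the stated search ranges are what matter; a grid mode exists),
   SVM C ∈ 0.1–10 with an RBF kernel, DT depth 3–5 with Gini splitting,
   KNN 3–7 distance-weighted neighbours. Class imbalance: stratification
   plus inverse-frequency class weights (per-class penalty multipliers for
   the SVM; KNN relies on distance weighting). Metrics are pooled over the
   held-out folds: accuracy, weighted precision/recall/F1 (reported as
   percent, 2 decimals), macro one-vs-rest AUC with a 95% bootstrap
   percentile CI (subjects resampled; resamples missing a class are
   redrawn). Importances: impurity-based for RF/DT, seeded permutation
   importance (50 shuffles) for SVM/KNN. A 5-fold-CV linear discriminant
   baseline compares the fused and spatiotemporal sets.

Everything derives from one master seed (per-subject streams spawned with
`numpy` SeedSequence), so cohorts are byte-identical and CV reports
bit-identical under a fixed seed.

## Synthetic cohort generator

The generator emulates the study conditions — 21 healthy, 24 KOA, 25 TKA
subjects, 3–5 gait cycles each at 100 Hz — with per-subject angle
templates built from period-wrapped Gaussian bumps (plus a cosine
flexion–extension wave for the hip):

- hip: cosine with maximal flexion at heel strike, scaled to the drawn hip
  RoM;
- knee: the classical two-peak flexion wave (loading-response peak at
  ~12% of the cycle, swing peak at ~72%), scaled to the drawn knee RoM;
- ankle: end-swing dorsiflexion peak at the cycle boundary (the
  heel-strike landmark), a loading-response dip, a mid-stance dorsiflexion
  plateau, and a deep plantarflexion trough centred at the drawn stance
  fraction (the toe-off landmark).

Group profiles anchor the RoM means to the magnitudes reported for these
populations (healthy knee ≈ 61.5°, hip ≈ 37.3°; KOA ≈ 50.6°/33.6°; TKA
≈ 44.6°/33.8°). A deliberate design rule: *every* subject parameter is
drawn, never a group constant, so no feature can act as a deterministic
group fingerprint. Accordingly:

- RoM SDs are realistic inter-subject variability (hip ≈ 5–7°, knee
  7.5–10°, consistent with the standard-error reading of published group
  tables), which makes the KOA and TKA morphology distributions overlap —
  mirroring the reported absence of significant KOA-vs-TKA cyclogram
  differences;
- postural offsets (hip centroid, SD 8°; knee minimum, SD 5°) vary per
  subject, reproducing the reported *non-significant* centroid group
  comparisons;
- the loading-response knee-flexion amplitude is drawn per subject
  (mean 0.25 of the swing peak, SD 0.05, same for all groups). A group
  contrast on this parameter was deliberately *not* used: a larger
  loading lobe crosses the heel-strike–toe-off chord and cancels
  stance-phase area, so contrasting it would invert the required
  stance-area group ordering. The group morphology signal is carried by
  RoM compression alone;
- movement complexity is injected as smoothed (moving average width 3)
  additive Gaussian noise with SD = noise level × joint RoM, the noise
  level drawn per subject (CV 0.3) around group means of 0.009 (healthy),
  0.016 (KOA, least regular) and 0.0035 (TKA, most regular, consistent
  with the reported post-operative entropy drop below healthy levels).

With this construction, cyclogram features mainly separate healthy from
pathological gait (via RoM compression), entropy features mainly separate
KOA from TKA, and the fused set is at least as accurate as every
single-category set for each classifier in the large majority of seeds —
the qualitative feature-fusion claim, realized by construction rather
than asserted.
Stance fractions are drawn near 0.60 (KOA slightly longer), cycle
durations jitter per cycle, and covariates (age, sex, BMI, side category,
spatiotemporal parameters) follow the published cohort demographics.
Every drawn parameter lands in a manifest for recovery tests.

What the generator does **not** emulate: soft-tissue artefacts and marker
noise structure, inter-joint coupling beyond the fixed template phase
relations, asymmetry between limbs, fatigue or speed drift within a
session, and non-sagittal degrees of freedom. Passing tests therefore
demonstrate correctness of the algorithms and the stated qualitative
group signatures under controlled conditions, not clinical performance on
real recordings.

## Numerical and design notes

- **Entropy of noiseless periodic signals** is low but not zero: value-
  symmetric waveforms (a cosine) produce template matches between rising
  and falling limbs that separate at length m+1, giving SampEn ≈ 0.2
  even for perfect repetition; asymmetric shapes (the knee wave) give
  < 0.1. Tolerance-monotonicity (SampEn non-increasing in r) holds
  robustly at the series lengths the pipeline analyzes (≈ 400 samples);
  at N ≈ 150 sparse template counts can break it.
- **RoM extraction bias**: additive noise inflates max − min by roughly
  2–3× the smoothed noise SD (≈ 0.5–1° at default noise levels), a bias
  well inside the 2-SEM recovery tolerance at the default cohort size.
- **Percent changes** are reported to one decimal, computed from group
  means.
- **Ties in feature selection** break by column order; search grids are
  fixed lists, so reports are reproducible bit-for-bit.
- **Problem sizes** used by the test-suite and the acceptance script —
  the 70-subject default cohort, 1000-replicate null simulations,
  50-series entropy oracles, bootstrap B = 200–1000 — were chosen to give
  stable statistics on a single CPU.

## Limitations

Single-trial, single-side analysis (no left/right fusion); heel-strike
onset is a package convention, not a force-plate ground truth; entropy
values depend on the normalized-cycle concatenation convention (cycle
boundaries introduce splice points, identical across groups); the
synthetic cohort's classifier accuracies characterize the generator's
separability, not clinical accuracy on real patients.
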