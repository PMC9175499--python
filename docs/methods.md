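# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, the conditions the synthetic-data generators emulate,
and what the tests do and do not establish about real data.

## Slide quantification

A slide is a set of tissue polygons (outer rings with optional holes) and
focus point marks in 0-based pixel coordinates (x right, y down), plus an
isotropic microns-per-pixel calibration; anisotropic calibrations are
rejected.  Ring areas use the shoelace formula with implicit closure and are
orientation-independent; a region's area is outer minus holes, regions are
summed **without** polygon union (the input contract forbids overlapping
annotations; a bounding-box overlap triggers a warning, not a merge).
Containment uses the even–odd rule with boundary points counted as inside, a
deterministic tie-break that retains marginal subpleural foci.  Polygonal
focus annotations are reduced to their centroid before containment testing:
the density only needs a count, and the centroid rule is deterministic.

Density is 100 × (in-tissue marks) / (tissue area in mm²); marks outside all
tissue are excluded, tallied and logged.  A slide with marks but zero tissue
area is an error; an entirely empty slide quantifies to density 0 with a
warning.  The p16-low/high cutoff defaults to 2.1 foci / 100 mm² but is a
configuration value throughout, so ROC analysis can re-derive it; the
boundary value itself classifies as low (class is high iff density > cutoff).

Foci are quantified per slide; when a subject contributes several slides the
cohort table carries one density per subject, chosen upstream.

## Cohort statistics

Sensitivity and specificity are computed from the confusion counts of a
predictor rule against a truth rule, with exact (Clopper–Pearson) binomial
95% intervals; an absent truth class raises an error naming the undefined
metric.  Performance metrics are displayed to 1 decimal place and cohort
proportions to the nearest integer; underlying files keep full precision.

The HRCT visual fibrosis score sums 0–4 extent grades over scan levels × 2
hemithoraces and rescales to percent of the maximum (8 × number of scans;
with the standard 4 levels the denominator is 32).

ROC analysis places thresholds at midpoints between consecutive distinct
marker values plus ∓∞ sentinels, calls a subject positive when value >
threshold, and computes AUC through the Mann–Whitney identity on midranks
(ties score ½).  The "best" cutoff maximises sensitivity + specificity
(Youden), with ties broken toward the smallest threshold so the reported
cutoff is the most inclusive.  The summed criterion lies in [1, 2]: 1 is
achievable by an all-negative rule, 2 is perfect separation.

## Survival analysis

The endpoint is composite lung-transplant-free survival: time from biopsy in
months to the first of death or transplantation; transplantation is an
**event**, not a censoring, and living subjects are censored at last
follow-up.  Records with non-positive follow-up are rejected with a log
entry.  Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines`; Greenwood variances are computed from the risk table
(`var S(t) = S(t)² Σ d/(n(n−d))`).

The Cox model is fit in-house by Newton–Raphson on the partial likelihood
with analytic score and information, covariates centered for conditioning,
and step-halving to guarantee ascent (the acceptance check uses a relative
slack of 1e-10·|ℓ| so float rounding near the optimum cannot stall the
line search).  Convergence requires max |score| < 1e-8 within 50 iterations.
Ties are handled by the Efron correction by default; Breslow is available by
flag and the two agree to < 1e-10 when no event times are tied.  Monotone
likelihood (perfect separation) is flagged via `converged=False` when |β̂|
exceeds 10 (hazard ratios above e¹⁰ are not interpretable in this domain).
Inference is Wald: CI = exp(β̂ ± 1.96·se), normal p-values.  Missing
covariate values and constant covariates are hard errors.  A unit test
cross-checks coefficients and standard errors against `lifelines` on the
same data, and a grid-search oracle on the exact partial likelihood pins the
4-subject case.

The multivariate model of interest uses p16-high and antifibrotic-treatment
indicators; age, sex, BMI, FVC% and DLCO% are available as screening
candidates.  A post-biopsy lung-cancer exclusion is a 0/1 flag column in the
cohort table, applied as a row filter, never inferred.

## Digital spatial profiling

QC drops ROIs below a total-count floor and genes below a mean-count floor
(housekeeping genes are never dropped); removing every ROI of a class is a
QC failure.  No outlier-probe rule is applied beyond these two filters;
probe-level tables can be collapsed to gene level by geometric mean.

Housekeeping normalization divides each ROI by
`geomean(housekeeping counts in ROI) / geomean over ROIs of those geomeans`;
a zero housekeeping count is a hard error naming the ROI and gene rather
than a silent pseudo-count.  Q3 normalization divides by the ROI's 75th
percentile (linear interpolation) over the geometric mean of all ROIs' 75th
percentiles.  Both are idempotent and invariant to global rescaling.
Housekeeping normalization feeds differential expression by default; the
choice is recorded in each run's manifest.

Differential expression uses Welch's t-test on log2(count + 1) per gene
(Mann–Whitney behind a flag for small-n robustness checks), with log2FC the
difference of class means on that scale.  The published study design is tiny
(12 vs 6 vs 6 ROIs), which motivates a simple location test over count-model
inference.  q-values are Benjamini–Hochberg step-up; genes are selected when
q < 0.05 and linear fold change ≥ 1.5 (inclusive, either direction).  A gene
with zero variance in both classes gets p = 1 when means are equal and p = 0
otherwise.  The headline contrast is focus vs pooled fibrosis + normal;
pairwise contrasts are available.

Clustering uses 1 − uncentered Pearson correlation (equivalently cosine
distance) with average linkage; zero-vector profiles are rejected.  Trees
are exported as Newick; heat-map export row-centers log2 values and scales
each gene by its maximum absolute value into [−1, +1].  PCA operates on the
row-centered log2 matrix with ROIs as samples, via SVD; components are
ordered by decreasing variance and signed so the largest-magnitude gene
loading is positive.

GSEA ranks genes by a signed score (signed −log10 p from the DE table, by
default) and accumulates a weighted running sum: member genes advance it by
their |score| weight normalised over the set, and every position retires the
uniform expectation 1/N, so the sum is a bridge ending at zero; the ES is
the extremum of largest magnitude.  With a single top-ranked member gene and
equal scores this yields ES = 1 − 1/N.  Because 6–12 ROIs cannot support
phenotype permutation, the null resamples same-size gene sets from the
ranked universe with a seeded RNG (default 1000 permutations); NES divides
ES by the mean |permuted ES| of matching sign, the nominal p counts
matching-sign permutations at least as extreme (with the +1 correction), and
the FDR q is the GSEA-style ratio of null-to-observed NES tail fractions
pooled across all tested sets, clipped to [0, 1].

## Synthetic data

The generators are pure functions of spec + seed and always return ground
truth alongside the data.

*Slides*: rectangles whose shoelace area equals the target exactly, with
uniform in-tissue marks and deliberate out-of-tissue marks.

*Cohorts*: diagnosis mix 60/19/13/7/1% (IPF / NSIP / unclassifiable /
chronic HP / smoking-related).  IPF density is zero-inflated lognormal
matched to the published summaries — zero fraction 12/52, positive median
1.97, σ = 1 on the log scale to span roughly 0.4–26 (per-case densities are
unpublished, so only these summaries are matched); non-IPF density is zero
except rare (3/34) low positives.  Survival times are exponential with
log-hazard = log(baseline) + β·covariates, β defaulting to the published
multivariate estimates (HR 2.40 for p16-high, 0.28 for antifibrotic);
censoring is an independent exponential clock (baseline 0.02 and censoring
0.015 events/month give ≈ 35% censoring, matching the published ~64%
combined event incidence).  The exponential baseline is chosen for
closed-form sampling and unbiased Cox recovery, not realism of the hazard
shape; it does not emulate delayed-entry, competing-risk or cure-fraction
features of real ILD cohorts.

*DSP*: negative-binomial counts (var = µ + αµ², default dispersion α = 0.1,
typical of targeted panels) around lognormal gene base means, scaled by
per-ROI lognormal depth factors; 31 housekeeping genes draw from a tighter,
higher base-mean distribution (real housekeeping panels are selected for
stable high expression — this also keeps their counts away from zero, which
the normalizer treats as an error); a 97-gene signature is up-regulated by
log2FC 2 in focus ROIs only.  The generator does not simulate probe-level
chemistry, background, or spatial correlation between ROIs.

A deterministic 86-subject "study structure" cohort reproduces the published
diagnostic and outcome marginals exactly (52 IPF with 40 any-focus and 21
p16-high cases; non-IPF densities 3.82, 1.08, 1.32; outcomes 31 alive / 13
transplanted / 42 died) for desk-checkable worked examples.  Within the IPF
p16-low positives the individual densities are an arbitrary deterministic
spread — only the marginal counts are meaningful.

Passing tests on these generators establish internal correctness (estimator
consistency, calibration, planted-truth recovery), not performance on real
slides or real GeoMX runs, whose artefacts (annotation error, segmentation
bleed-through, batch effects) are not modelled.

## Problem sizes and tolerances

Recovery checks use 50 replicates at n = 2000 (univariate) and n = 3000
(multivariate) cohorts, sizes at which the Monte-Carlo standard error of the
mean hazard-ratio estimate is ≈ 0.02, comfortably inside the ±0.15
acceptance band; log-rank null calibration uses 200 replicates of 60-subject
cohorts; DE null calibration uses 100 replicates of 500-gene experiments.
Geometry oracles (shoelace vs an independent polygon library, even–odd vs
winding number) run on seeded random star-shaped polygons.  Numerical
tolerances: Cox gradient 1e-8; normalization idempotence 1e-10; PCA oracle
agreement 1e-8.

## Known limitations

- The cohort generator draws covariates independently; real PFTs, age and
  density are correlated, so covariate-adjustment behaviour under
  confounding is not exercised.
- Proportional hazards are true by construction in the simulations; no PH
  diagnostics beyond a log(−log) export are provided.
- The recomputed specificity of p16-high for IPF from the published
  cross-tabulation counts is 33/34 = 97.1%; the originally reported 97.6%
  cannot be reproduced from those counts and is documented here rather than
  targeted.
- The published prose hazard ratio for antifibrotic therapy (2.64,
  "protective") is inconsistent with the printed multivariate table (0.28,
  0.10–0.66); the table value is used as the generating truth.
- Storey q-values, competing-risks models, time-varying covariates,
  negative-probe background modelling and pixel-level image analysis are out
  of scope.
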