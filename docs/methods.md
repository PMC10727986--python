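# Methods

`mesovasc` implements a quantitative-morphometry pipeline for two-band
optoacoustic mesoscopy (RSOM) skin scans: synthetic phantom generation,
preprocessing, two-step segmentation, skeleton-graph feature extraction, a
composite diabetes ("microangiopathy") score, and ordinal disease-stage
modelling.  Because no public RSOM dataset of this kind exists, every stage
is validated against synthetic skin volumes whose ground truth is known by
construction.  This note records the models, the defaults and why they were
chosen, what the phantoms do and do not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Coordinate and unit conventions

Arrays are indexed `[z, y, x]`, z pointing into the skin; all geometry is in
micrometres with explicit voxel spacing carried on every container.  The
defaults mirror the instrument raster: a 4 × 2 mm scan, 15 um steps along x,
7.5 um along y, ~4 um depth sampling, ~2 mm depth.  Physical units matter
because the spacing is anisotropic: skeleton branch lengths, diameters and
densities are all calibrated by the spacing, never by voxel counts alone.

## Phantom model

A phantom is a layered slab — a thin epidermal/SVP band above a thicker
dermal band, with an optional sinusoidal interface undulation — populated by
vessel networks built from three motif primitives: straight segments, "Y"
bifurcations (1 junction, 3 endpoints) and "H" bridges (2 junctions, 1
junction-to-junction branch).  Motifs are placed by rejection sampling with
a guaranteed minimum clearance between structures, so the planted graph
counts (vessels, junctions, endpoints, j2j/j2e branches) are exact by
construction and recoverable by skeleton analysis whenever the tube radius
is at least 2 voxels and the clearance at least 4 voxels.  A `planar` mode
confines motifs to the (z, x) plane for validating the 2D (projection) path
without projection-overlap ambiguity.

Rendering assigns each tube an HF/LF band weight that is monotone in radius
— HF weight `exp(-r / 50 um)`, LF the complement — emulating that small
structures emit high ultrasound frequencies.  With zero noise the per-voxel
HF+LF intensity equals the assigned amplitude exactly.  Noise is additive
zero-mean Gaussian (default sigma 5% of peak) with an optional salt-speckle
term; intensities are deliberately not clipped at zero so the perturbation
stays exactly zero-mean.

Cohorts assign each participant a private RNG stream derived from
`(master seed, participant index)`, so any participant's volumes are
reproducible independently of cohort size or generation order.  Planted
group effects are expressed as per-feature multipliers mapped onto generator
knobs (motif rates, radius/length scales, band thickness); the shipped
default profiles encode the published directions of change — dermal network
features fall with disease stage, epidermal/SVP features rise.  The healthy
baseline rates are order-of-magnitude choices (no quantitative distributions
for healthy skin exist in the source material) and are fully config-exposed.
A fast feature-level simulator draws feature vectors directly from the
planted rates (Poisson for counts, Gaussian otherwise) for Monte-Carlo
statistics that do not need image rendering; the image path is validated
separately by the graph-recovery suite and the end-to-end pipeline test.

What the phantoms do **not** emulate: optoacoustic wave propagation and
reconstruction artifacts, melanin absorption, motion, vessel tortuosity and
tapering, and anatomically realistic network topology.  Passing tests
therefore demonstrate the correctness of the measurement and modelling
machinery, not clinical performance on real skin.

## Preprocessing

Maximum-intensity projection along y per frequency band, per-channel
normalization to unit maximum, and red=HF / green=LF / blue=empty RGB
composition.  For the 2D segmentation path, images are resampled bilinearly
to a fixed 768 × 256 (depth × lateral) raster — the network-output geometry —
and collapsed to grayscale by the channel mean.  Which image dimension maps
to 768 is not documented in the source; depth × lateral is the assumption
used throughout and is config-exposed.

## Segmentation

Two steps: skin-layer masks, then vessel masks inside each layer.  The
implemented vessel route is the classical reference chain — grayscale →
Sato multiscale Hessian tubeness (default sigmas {1, 2, 4} px) → adaptive
local-mean thresholding (default block 51) — restricted to each layer mask,
with containment enforced.  This chain is also how the reference vasculature
masks were produced for the published deep-learning variant, so it is the
method of record here; a trained U-NET alternative is not part of this
build (no deep-learning framework is a dependency), and requesting it
raises.  The pixel-wise binary cross-entropy loss used to train such
networks is implemented in numpy on the fixed raster and verified against
its closed-form values.

Adaptive-threshold offset convention: a pixel fires when it exceeds its
local block mean **by more than `offset`**, so a positive offset is a
sensitivity floor and a constant image yields an empty mask.  The library
default is offset 0; the demo pipeline uses 0.08 because with 5% rendering
noise a zero offset admits roughly half of the background.  Layer masks in
the pipeline come from phantom ground truth, standing in for the manual
expert delineation used with clinical data.  3D vessel masks are produced by
running the 2D chain on every y-slice and stitching (`out[z,y,x] =
slice_y[z,x]`), mirroring the published slice-wise protocol.

Mask agreement is quantified by the Dice score, Cohen's kappa (computed from
the pixel confusion matrix) and the Hausdorff distance taken over boundary
pixels (8-connectivity) in pixel units, as the max of the two directed
distances.  Conventions: two empty masks agree perfectly (Dice 1, kappa 1,
Hausdorff 0); exactly one empty mask gives infinite Hausdorff distance.

## Skeleton-graph morphometry

Vessel masks are thinned with Lee's method in both 2D and 3D.  Lee's scheme
is used in 2D as well (not the default Zhang thinning) because Zhang erodes
narrow ~45-degree diagonal branches from the tip inward — the tip of a
2-wide diagonal staircase never becomes a protected single-neighbour
endpoint — which silently deletes whole branches at small radii.

The skeleton is decomposed into a graph: node voxels are skeleton voxels
with ≠2 neighbours (8-/26-connectivity); adjacent node voxels are merged
into one node so thinning clumps at junctions do not inflate counts; a node
is a junction if any member voxel has ≥3 neighbours, else an endpoint.
Branches are voxel paths between nodes, typed j2j / j2e / e2e / cycle, with
length the spacing-calibrated sum of inter-voxel steps.  An optional spur
prune removes j2e branches shorter than a threshold and rebuilds (default
off — the recovery suite passes without it).  Vessel diameter is estimated
as twice the Euclidean distance transform (anisotropic sampling) averaged
over skeleton voxels — the standard medial-axis estimator.

Sixteen features per (layer × dimensionality) subgroup, 64 per image:
vessel count (= connected skeleton components), junction / j2j / j2e /
endpoint counts, average vessel (component) length, average branch length,
total skeleton length, average vessel area (2D) or volume (3D), total vessel
area, average diameter, vessel density (vessel ÷ layer pixels), layer area,
layer thickness (mean per-column z-extent), junction density and endpoint
density.  Where the source names only some of the 16, the remainder are
canonical morphometry choices and are flagged as such; "number of vessels"
reads as skeleton components (the most explainable, oracle-checkable
definition), and "average vessel length" averages per component (the
per-branch average is emitted separately).  Undefined averages on empty
masks are reported as 0 with an explicit flag rather than as missing values,
so downstream feature matrices stay complete.  Each feature carries a scale
label — microscale (<100 um, single-vessel dimensions), mesoscale
(~100–1000 um, network organization), macroscale (>1000 um, whole-region
geometry).  The 32 published diabetes-relevant features ship with their
tabulated labels in a versioned JSON resource; all other keys use the rule
stated above, and the two assignments agree on every published key.

## Microangiopathy score

Features (optionally reduced to the top k by univariate ANOVA-F, default
k = 32) feed a random forest — 100 trees, unlimited depth, Gini criterion —
evaluated by leave-one-subject-out cross-validation: all images of the
held-out participant are excluded from training, asserted structurally on
every run.  The participant score is the mean positive-class probability
over that participant's images, with the across-tree standard deviation as
its uncertainty.  Forests default to `class_weight="balanced"`: every LOSO
training fold is short one sample of the held-out participant's class, and
unweighted forests therefore score held-out participants slightly against
their own class (a visible AUC deflation under label permutation).

The operating threshold maximizes the Youden index J = SNS + SPC − 1 over
midpoint candidate cuts, verified against exhaustive search; ties resolve to
the middle of the lowest optimal plateau.  Metrics follow the printed
confusion-count formulas (ACC, SNS, SPC, PPV, NPV) plus F1, the Matthews
coefficient normalized to [0, 1] via (MCC+1)/2, and the AUC; empty
denominators flag the metric as undefined instead of silently reporting 0.
Supporting analyses: nested cross-validation (outer LOSO, inner 4-fold grid
over forest size, max-features and k; default grids {50,100,200} ×
{sqrt,log2,all} × k ∈ [10,64]), percentile-bootstrap confidence intervals on
an independent test set, a cohort-imbalance check comparing the healthy
group against many random fixed-size patient subgroups (default 5000 × 40),
Gini impurity-decrease feature importances, and per-clinical-subgroup
correct/incorrect proportions.

## Ordinal stage model

Stages A < B < C are modelled by a cumulative link model
`G⁻¹[P(Y ≤ j)] = a_j − Xβ` with strictly ascending thresholds; the link is
logistic by default, probit by config (the source does not name G).
Features are z-scored before fitting for optimizer stability; coefficients
are reported on both scales.  Fits use maximum likelihood (statsmodels
`OrderedModel`, BFGS); the intercept-only model uses its closed form
`a_j = G⁻¹(cumulative class fraction)`, which is the exact MLE.
Non-convergence and non-ascending thresholds are flagged on the result.

Term selection is two-stage, balancing parsimony and predictive power:
greedy bidirectional stepwise search minimizing AIC from the intercept-only
model over main effects plus pairwise interactions (the interaction pool is
capped, default 50 columns, by a univariate F screen — the full pairwise
space of 32 features is 496 terms), followed by leave-one-out accuracy
elimination that drops any term whose removal does not reduce LOO accuracy.
Scale importance is the in-sample accuracy decrease after removing each
scale's features and refitting; boxplot statistics come from random
within-scale subsets (default 200), reported as the median and the central
85% interval — an explicit operationalization of an ambiguously described
summary, not a claim about the source's exact procedure.

Monotone trends flag features whose stage-group means are strictly ordered
A→B→C, with pooled-variance two-sided t-tests per contrast (zero pooled
variance with equal means returns p = 1 by convention).  Confounder control
fits three nested binomial-logit GLMs — covariate only; + score; +
interaction — and compares them by chi-squared tests on deviance differences
(df = number of added terms), flagging separation.

## Problem sizes used by the test and acceptance suites

The suites run on scaled-down phantoms and cohorts chosen as desk-scale
study conditions: graph-recovery phantoms are ~90³ voxels at 10 um isotropic
spacing with radius ≥ 2 voxels and clearance ≥ 4 voxels (50 seeds, both
layers); the demo pipeline cohort is 12 healthy + 6 per stage at a
1.2 × 0.6 × 1.3 mm field; the permuted-label null uses 200 participants and
100 permutations; CLM parameter recovery uses 50 replicates at n = 500; the
scale-importance study uses 50 cohorts of 75 staged participants.  Forest
sizes in the Monte-Carlo null are reduced from the 100-tree default (forest
size is a configuration, not a study condition); all other stated conditions
are kept as is.

## Known limitations

* Graph-count recovery guarantees hold for the motif-based phantoms in the
  stated radius/clearance regime; dense anastomosing networks can merge
  under rasterization and are outside the guarantee.
* The 3D "total area of vessels" is a voxel volume (um³); the name follows
  the published feature table.
* The classical vessel path over- or under-segments near layer boundaries
  on noisy renderings; the demo threshold offset (0.08) trades recall for
  precision there.
* The deep-learning segmentation variant and tomographic reconstruction are
  out of scope; clinical headline numbers are not reproducible without the
  non-public patient data and are not targets of this package.
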