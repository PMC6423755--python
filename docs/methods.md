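# Methods

`ngahic` implements a quantitative-histomorphometry pipeline for predicting
recurrence in node-negative gastric adenocarcinoma from H&E-stained
tissue-microarray (TMA) spot images, together with a synthetic-data generator
that reproduces the statistical structure the analysis assumes. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not establish.

## Imaging model and segmentation

A spot image is an H×W×3 intensity raster at a nominal 0.25 µm/pixel (40×
scan). Stain separation follows the Beer–Lambert model: optical density
`OD = -log10(I / I0)` per channel, projected onto a 3×3 stain basis whose
rows are the unit-norm absorption spectra of hematoxylin, eosin and a
residual channel (the standard published H&E basis, overridable per slide).
A pure-background pixel maps to exactly zero density in all three channels;
negative projections are clipped to zero.

Nuclei are segmented on the hematoxylin channel: light Gaussian smoothing
(σ = 1 px) → Otsu threshold → hole filling → Euclidean distance transform →
Gaussian-smoothed distance (σ = 2 px) → local maxima (min separation 7 px)
as markers → marker-controlled watershed with 4-connectivity → area filter
(30–5000 px² at 0.25 µm/px, i.e. ~2–300 µm²). Touching nuclei are split at
watershed lines between distance peaks. An image with no detectable
foreground yields an empty mask with a warning, not an error.

Per nucleus we keep the 0.5-level boundary polygon (sub-pixel, ≥8 vertices),
pixel area, polygon perimeter, the second-moment ellipse-fit orientation
mapped to [0°, 180°), eccentricity, and the per-channel intensity patch with
its interior mask. Nuclei with eccentricity < 0.05 have no meaningful major
axis; they receive orientation 0° by a fixed tie-break and are excluded from
orientation co-occurrence statistics so an undefined angle cannot distort
them.

## The 189-feature vector

Five families, fixed order and naming, 189 features total.

**Shape (100).** Twenty-five descriptors per nucleus × {mean, SD, median,
min/max ratio} across nuclei. The descriptors: area ratio (polygon area over
its minimum enclosing circle), max/min centroid-distance ratio, SD and
variance of the centroid-distance signature (128 equal-arc-length samples),
min-distance/mean-distance ratio, perimeter-to-convex-hull-perimeter ratio,
box-counting fractal dimension of the boundary, boundary smoothness (mean
absolute second difference of the distance signature), the seven Hu
invariant moments of the filled polygon, and the magnitudes of Fourier
harmonics 1–10 of the distance signature normalized by harmonic 0.

Hu moments are computed *analytically from the boundary polygon* via
Green's-theorem edge integrals (exact polynomial quadrature per edge), not
from a raster. On small nuclei raster moments lose several digits to
discretization; the polygon route keeps rigid-motion and scale invariance at
float precision (verified at 10⁻³ relative tolerance, typically 10⁻¹⁰).
Published inventories of this feature family list "distance ratio" twice;
the duplicate slot is filled here by the min-distance/mean-distance ratio so
that 25 descriptors × 4 statistics equals the canonical 100.

The fractal dimension uses box counting on 4096 boundary samples over grids
2³…2⁸, skipping the 2×2 and 4×4 grids where every curve saturates the count
and biases the slope upward; the result is clipped to the admissible [1, 2].
A smooth ellipse measures ≈1.03.

**Texture (30).** Per nucleus and channel (raw R, G, B), a gray-level
co-occurrence matrix: 8 levels, distance 1, four directions, symmetrized and
direction-averaged, computed over the nuclear interior only (exterior pixels
carry a sentinel level whose rows/columns are discarded, so no pair straddles
the boundary). Descriptors: contrast, energy (angular second moment),
entropy in bits, inverse variance (Σ_{i≠j} P/(i−j)²), plus the first Hu
moment of the masked intensity patch. Aggregation: {mean, SD} across nuclei
→ 5 × 3 × 2 = 30. Nuclei with fewer than 9 interior pixels are skipped with
a log entry. Energy = 1 ⟺ entropy = 0 (single-entry matrix) holds by
construction.

**Orientation co-occurrence (39).** Each defined orientation is quantized
into 18 bins of 10° over [0°, 180°). For each nucleus, a symmetric
normalized 18×18 co-occurrence matrix of (own bin, neighbor bin) over its
k = 5 nearest neighbors; from it the 13 Haralick-family descriptors
(contrast energy/inverse moment/average/variance/entropy, intensity
average/variance/entropy via the sum- and difference-histograms, entropy,
energy, correlation, and the two information measures of correlation).
Aggregation: {mean, SD, range} → 39. When fewer than half the nuclei have a
defined orientation the computation proceeds on the defined subset with a
warning. B = 18 and k = 5 are configurable; they are conventional values for
orientation-disorder features on nuclear graphs.

**Voronoi (12) and Delaunay (8).** The Voronoi tessellation of nuclear
centroids is clipped to the image box; boundary cells are clipped rather
than discarded because small synthetic spots would otherwise lose most
cells. Per cell: perimeter, area, and mean chord — for each vertex, the
length of the full chord through the cell centroid, averaged; "chord" has no
single standard definition for Voronoi cells, so this reading is documented
as an interpretation. Aggregation per attribute: {average, SD, min/max
ratio, disorder} → 12. The Delaunay triangulation contributes edge lengths
and triangle areas with the same four statistics → 8; the canonical count of
8 admits exactly four aggregate statistics per attribute, so the
four-statistic set {min/max, mean, SD, disorder} is used (a five-statistic
reading would give 10 and is inconsistent with the count).

The disorder statistic is `1 − 1/(1 + SD/mean)`: zero exactly when all
values are equal, strictly below one, monotone in the coefficient of
variation. SDs use the n−1 normalization throughout; a single-element
sample has SD defined as 0.

## Selection, classifier grid, recurrence call

Three ranking schemes on the training cohort: two-sided Wilcoxon rank-sum
p-value (midrank ties, exact null when both groups have ≤8 samples,
asymptotic otherwise; a constant feature gets p = 1 by convention), greedy
MRMR on 4-quantile-binned features maximizing I(f; label) minus the mean
mutual information with already-selected features (bits), and mean
impurity-decrease importance of a seeded random forest. Each runs inside
stability selection: stratified 3-fold × 100 iterations, rank within every
training fold, and keep the 5 features most frequently present in the
fold-level top-5 lists (ties by mean rank, then name). The protocol never
specifies how fold-level rankings combine; selection frequency is the
standard choice and is documented as ours.

The grid crosses four learners with the three bins (12 combinations):
linear discriminant (lsqr solver, automatic shrinkage), a
shrinkage-regularized Gaussian quadratic discriminant (class covariances
shrunk toward scaled identity with weight 0.2 — required because a 5-feature
bin routinely exceeds the per-class sample count in a 60-patient cohort),
a linear SVM (C = 1) with held-out-fold sigmoid probability calibration, and
a 100-tree random forest. Discriminants and the SVM see z-scored features
(training statistics); the forest sees raw values. Metrics (AUC, accuracy,
specificity, sensitivity) are fold-averaged over repeated stratified 3-fold
cross-validation and reported as mean ± SD; fold-averaging (rather than
refit-on-full metrics) is our documented reading of an ambiguous protocol.
The best combination by mean AUC — ties broken by accuracy, specificity,
sensitivity, then fixed learner/bin order — is the NGAHIC. A spot is called
recurrence-positive iff its predicted probability strictly exceeds 0.5.

## Survival and association statistics

Kaplan–Meier product-limit curves with right censoring; the two-group
log-rank test (observed-minus-expected with hypergeometric variance); Cox
proportional-hazards regression with Efron tie handling, Wald confidence
intervals and p-values (lifelines). A monotone partial likelihood (a
covariate that perfectly separates the risk sets, which a 17-fold hazard
ratio occasionally produces at n = 100) is detected and raised as an error
rather than silently reported as a huge unstable estimate; the pipeline
records such cohorts with a warning. Two multivariate covariate sets are
supported — the compact adjustment (T-stage, histology grade, invasion
depth) and the extended one adding manual grade and tumor diameter —
since the source is ambiguous about which was used; neither is asserted
canonical. The endpoint (overall vs disease-specific survival) is a flag.

2×2 associations between classifier calls and HER2/Ki67 status use
two-sided Fisher's exact test (point-probability rule) or the classic
uncorrected 1-df chi-square; the uncorrected statistic is used so it matches
the textbook formula exactly. Ki67 is positive at a labeling index ≥ 14%.

## Synthetic-data generator

The generator defines the study conditions for every experiment.

**Spots.** Nuclei are filled ellipses with Gaussian-blurred edges (σ = 1 px)
and additive Gaussian stain noise (SD 5 intensity units) on a pink
background, nucleus color dark blue-violet. Areas follow a gamma law with
mean 300 px² (~8.7 µm equivalent diameter at 0.25 µm/px) and configurable
coefficient of variation; eccentricities are uniform on a configurable
range; orientations follow an axial (180°-periodic) von Mises law with
concentration κ (κ = 0 uniform, large κ aligned). Placement is uniform at
clustering 0 and Thomas-process-like (Gaussian scatter around ~n/10 parent
points, spread shrinking with the clustering parameter) otherwise; overlaps
are resolved by rejection sampling up to 200 retries per nucleus, after
which the overlap is accepted and logged. Requests whose total nuclear area
exceeds 80% of the canvas are rejected. The default canvas is 1024 px —
deliberately far smaller than a real 2-mm core (8000 px) so experiments run
at desk scale; tests use 256–512 px.

**Cohorts.** Patients are recurrence-positive with a configurable fraction
(default 0.225, matching 36/160 in the emulated cohort). Positive patients
receive high-disorder spot parameters (κ = 0.3, area CV 0.45, clustering
0.6) and negatives low-disorder ones (κ = 4, CV 0.2, clustering 0.2).
Survival times are exponential — the source does not describe its event-time
distribution, and a constant hazard makes the proportional-hazards
assumption hold exactly — with baseline hazard 0.02/month (median ≈ 35
months, matching the reported ≈38-month median) scaled by the hazard ratio
(default 17.24) for positives; censoring is an independent uniform time on
(0, follow-up cap) applied with the censor-rate probability, plus
administrative censoring at the 60-month (5-year) follow-up cap. A
spot-free feature matrix is drawn alongside: standard normal in all 189
named features, with a configurable standardized mean shift (default 1.5 SD)
added to five designated features for positive patients; the defaults mirror
the study's top-5 discriminative set (range of intensity entropy, range of
energy, SD of perimeter ratio, SD of intensity average, disorder of
perimeter). IHC columns are Bernoulli per group at configurable rates
(defaults 81.3%/3.6% for HER2, 75%/2.4% for Ki67), with the Ki67 status also
derivable from a simulated labeling index thresholded at 14%.

What the generator does *not* emulate: chromatin texture beyond stain noise,
stromal/epithelial compartments, nucleoli, staining gradients, scanner
artifacts, and correlated feature noise. Passing tests therefore establish
that the pipeline recovers the structure it assumes — not that it would
reach the same operating point on real slides, whose headline cohort values
depend on unreleased patient images.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations produce byte-identical
outputs, and the run manifest records the configuration hash and derived
stage seeds. The stability-selection protocol default is 100 iterations; the
repeated-experiment suites (20-seed AUC recovery, pipeline runs) use 25
iterations and 50 trees inside the ranking loop, sizes at which the selected
bins are already stable for the default effect size. Calibration experiments
use the sizes their designs call for: 20 seeds of 60-train/100-test for the
held-out AUC regime, 100 replicates of balanced two-group exponential data
at n = 500 for Cox recovery of HR = 2, and 1000 null replicates at n = 100
for the log-rank type-I error.

## Known limitations

* Watershed splitting is tuned for moderately dense spots; at extreme
  clustering merged nuclei are under-segmented, which the area filter only
  partly corrects.
* The stability score of the best pure-noise feature is typically 0.4–0.8,
  not near 5/189: fold-level rankings reuse the same sample, so a lucky
  feature is persistently lucky. Stability scores separate signal from noise
  only together with effect size, not as calibrated probabilities.
* The Voronoi "chord" statistic is one reasonable reading of an undefined
  term; alternative readings (ridge lengths) would change those 4 features.
* Synthetic feature matrices have independent Gaussian noise; real
  morphometric features are heavily correlated, which would lower effective
  dimensionality and change MRMR behavior.
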