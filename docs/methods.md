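# Methods

This note documents the models implemented in `gfkuts`, the defaults
and why they were chosen, what the synthetic data emulates, and the
numerical choices a maintainer should know about.

## Segmentation pipeline

### Trimap initialisation

`l` pixels (default 1000) are drawn uniformly at random **with
replacement**; duplicates collapse to one coordinate in the masks.
Binary K-means runs on the sampled colour vectors (the full composite,
up to 4 channels). Cluster-to-class assignment uses plot-imagery
structure: the larger cluster is canopy, the smaller soil. An exact
size tie is broken towards the cluster with the higher mean NIR
(vegetation reflects NIR strongly). Degenerate input (all sampled
colours identical) raises.

Lloyd iterations (max 100, tol 1e-6 on centroid motion) are seeded by
**multi-restart random initialisation** (8 restarts from random distinct
data points, lowest within-cluster sum of squares wins). A
farthest-point seed was tried first and rejected: it deterministically
places a centroid on the brightest outlier, and on scenes with clipped
highlights it locks into an outlier-versus-rest partition whose inertia
is roughly twice that of the canopy/soil split. Random restarts find
the better optimum reliably and stay deterministic under the seed.

### GrabCut engine

* Per-class colour models: K = 5 full-covariance Gaussian components
  (classic choice; configurable), fitted GrabCut-style — seeded K-means
  partition, then one hard maximum-likelihood reassignment and
  re-estimation per outer iteration, never full EM. Covariances get
  +1e-6·I jitter, escalated if Cholesky still fails.
* Data term U: full per-class mixture log-likelihood (not hard
  component assignment); likelihoods floored at 1e-300 before the log.
* Smoothness term V: 8-connectivity, γ = 50 (configurable),
  β = 1/(2⟨‖z_p − z_q‖²⟩) estimated once per scene over all neighbour
  pairs, diagonal pairs down-weighted by 1/√2.
* Min-cut: `scipy.sparse.csgraph.maximum_flow` on the standard s/t
  graph. The solver needs integer capacities that fit int32, so float
  energies are scaled by 2²⁰ and rounded; frozen trimap pixels carry a
  2³⁰ terminal capacity. Consequently a returned labeling is optimal up
  to the quantisation bound (#links × 2⁻²⁰ ≈ 10⁻⁴–10⁻² energy units
  depending on image size); the exhaustive-enumeration tests assert
  optimality up to exactly that bound. Because negative log-likelihoods
  can be negative (pdf > 1), the per-pixel minimum class cost is
  subtracted from both terminal links before scaling — a shift of E by
  a labeling-independent constant.
* Iteration: uncertain pixels start as possible foreground; GMM refit
  and min-cut alternate for n iterations (default 5) or until α stops
  changing. T_F / T_B pixels stay frozen throughout.

### Guided-filter refinement

Box means are computed with an integral image; border windows are
normalised by their actual pixel count. The filter follows the standard
O(n) coefficient form (a = cov(I, p)/(var(I) + ε), b = μ_p − a·μ_I,
output = ⟨a⟩·I + ⟨b⟩); on interior pixels this equals the explicit
weighted-average kernel, which the tests verify directly. Multi-channel
guidance filters per channel and averages the outputs; a
higher-resolution guidance (e.g. an RGB reference) is supported by
bilinearly upsampling the mask first. Defaults r = 8 px, ε = 1e-3 at
the 256×256 default scene size; batch runs at 96×96 use r = 4 (radius
scaled with scene size).

The adaptive threshold is Otsu's global histogram threshold by default
(parameter-free, reproducible); a Gaussian local-mean variant with
window 2r+1 is selectable. A constant soft mask has no threshold and
returns all-background with a warning.

### Canopy orientation

The cluster-size rule makes "foreground" the majority class, so on
scenes where canopy covers less than half the plot the raw pipeline
would segment soil. `run_gfkuts` therefore ends with an orientation
step (on by default): the side of the final mask with the higher mean
NDVI is reported as canopy, falling back to mean NIR when no red band
is present. NDVI rather than raw NIR because a sparse young canopy can
reflect less NIR than bright dry soil, while its NDVI is always higher
(soil red is high). The trimap itself keeps the cluster-size rule.

### Evaluation

Metrics are computed over region×region tiles (default 10×10),
macro-averaged: accuracy over all tiles; precision skipping tiles with
no predicted positives; recall skipping tiles with no positive truth;
F1 from per-tile precision/recall where both are defined (0 when both
are 0). Partial edge tiles count with their actual size. A
micro-average (pool all counts first) is available; macro is the
default. Baselines for comparison: global Otsu on the NIR band, and
whole-image binary K-means on colour with the higher-mean-NIR cluster
as canopy.

## Vegetation indices

Seven indices from the four camera bands, with the wavelength-to-band
identification ρ_780/ρ_800 → NIR, ρ_670 → red, ρ_500 → green (red-edge
is guidance-only):

NDVI, GNDVI, DVI, CTVI = sign(NDVI+0.5)·√|NDVI+0.5| (the standard
corrected-transformed form), SAVI with L = 0.5, MSAVI (closed form),
SR. Pixels with zero denominators are flagged invalid and excluded from
the plot mean; aggregation is the arithmetic mean over canopy pixels
(median selectable). Correlations use the conventional Pearson
product-moment formula; constant columns are marked undefined (NaN) in
the correlation matrix.

## Biomass models

### Elastic net

Loss: MSE + r·α·Σ|β_i| + ((1−r)/2)·α·Σβ_i², intercept unpenalised,
r ∈ [0, 1] mixing ridge (0) and lasso (1). Fitted by cyclic coordinate
descent with soft-thresholding; converged when the largest coefficient
change in a sweep is below 1e-8, hard error after 200 000 sweeps.
Features are z-scored and the response divided by its standard
deviation before descent (glmnet's convention), so α is interpreted on
the standardized problem — necessary because biomass is of order
10²–10³ g while the VI features are O(1). Coefficients are returned on
the original scale. The α = 0 limit is solved directly by least squares:
without a penalty the objective loses strong convexity and coordinate
descent crawls on the near-collinear VI set (NDVI, SAVI, DVI and MSAVI
are correlated above 0.99). α and r can be chosen by 5-fold
cross-validated grid (`select_hyperparams`); the library default is a
small fixed α = 1e-3.

Genotype analysis fits one elastic net per production system and
reports, per system, the difference of genotype-wise mean residuals
divided by the pooled residual SD — near 0 when the features explain
everything the genotypes do, large when a genotype adds biomass the
canopy reflectance cannot see.

### Neural network

One hidden layer, 15 tanh units, linear output (activations are a
design choice; common for Levenberg–Marquardt regression networks).
Training minimises the sum of squared residuals with LM: damped normal
equations (JᵀJ + λI)δ = Jᵀe on the analytic Jacobian, λ ÷10 on an
accepted step and ×10 on a rejected one (cap 1e10). Inputs and target
are z-scored on the training split.

The data enter as a 60/40 train/test split. A fifth of the training
split is held out for **validation-based early stopping** (patience 6
accepted steps, best-validation weights restored): the 7→15→1 network
has 136 parameters against ~70 effective training rows at the trial
sizes used here, and LM run to convergence interpolates the training
set — test correlation then collapses on some seeds even though a
linear fit reaches r ≈ 0.99. Early stopping is the standard companion
of this optimiser in neural-network toolboxes and removes the failure
mode without touching the architecture. A per-stage training mode
(`--per-stage`) fits one network per phenological stage instead of one
across all stages.

## Synthetic data

The generator produces what the pipeline assumes about plot imagery,
with exact ground truth:

* **Canopy geometry**: thresholded sum of anisotropic Gaussian bumps
  plus a sinusoidal ripple, thresholded at the quantile matching the
  target canopy fraction — boundary complexity at leaf scale without
  ray tracing; generation is vectorised and sub-second.
* **Reflectance**: class-constant band means (canopy NIR 0.60, red
  0.08, green 0.15, red-edge 0.40; lowland soil dark/water-like, upland
  soil bright) plus i.i.d. Gaussian band noise (default sd 0.02),
  clipped to [0, 1].
* **Artifacts**: a multiplicative shadow patch (dim factor 0.55–0.75
  over 2–10 % of the scene — a cast shadow after sunshine-sensor
  compensation, not a blackout) and a small clipped-highlight patch
  (blend towards white, opacity 0.5–0.75, texture preserved).
  Severities are chosen so artifacts perturb the colour distribution
  without creating a tight third mode far from both classes; a distant
  constant patch makes outlier-versus-rest the *global* binary 2-means
  optimum, a regime in which no 2-cluster initialisation can work and
  which compensated field imagery does not exhibit.
* **Trial structure**: stage mean dry biomass 200/600/1000 g per plot
  (sd 15 %), water content 0.85/0.70/0.50 declining by stage
  (fresh = dry/(1−wc)), canopy fraction rising 0.40/0.60/0.75. Canopy
  NIR is tied to biomass through the saturating map
  NDVI = 0.95·BM/(250 + BM) at fixed red, then inverted to a
  reflectance — so NDVI loses sensitivity at high biomass as dense real
  canopies do. The IR64 genotype carries a positive biomass offset
  (+10 % lowland, +18 % upland) that is **stature-mediated**: it is
  added after the reflectance is derived, so it is invisible to the
  canopy image and shows up only as residual structure — which is what
  the genotype-separation statistic measures.
* **Stress suite**: 50 scenes sweeping canopy fraction 0.3–0.8 and band
  noise sd 0.10–0.20, shadow and overexposure each with probability
  0.7, alternating soil systems. The noise range starts where per-pixel
  clustering begins to degrade; below sd ≈ 0.1 every method saturates
  near F1 = 1 on these scenes and the comparison is uninformative.

What passing tests on these scenes do **not** show: robustness to
geo-registration error, mixed vegetation (weeds), within-class
reflectance gradients, row structure, or specular water glint patterns
— real-field effects the generator does not model. The synthetic
closure numbers (segmentation F1, biomass r/R²) characterise the
implementation under its stated assumptions, not expected field
performance.

## Problem sizes

Default single scenes are 256×256 px. Batch sweeps and the pipeline
closure run use 96×96 scenes with l = 600 samples and guided-filter
radius 4, 150 scenes per trial (50 per stage) — sizes chosen so the
full synthetic study runs in about a minute on one core while leaving
every stage's behaviour intact.

## Known limitations

* The trimap freezes every sampled pixel; sampling errors (a mislabeled
  sample inside an artifact region) are unrecoverable by construction.
  The pipeline accepts this in exchange for full automation.
* Binary colour clustering cannot separate canopy from soil when a
  third colour mode (severe artifact) dominates the distribution; see
  the artifact-severity discussion above.
* Min-cut optimality is exact only up to integer-capacity quantisation
  (2⁻²⁰ per link).
* The guided filter treats multi-channel guidance channel-by-channel;
  the full colour-covariance variant is not implemented.
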