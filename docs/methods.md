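# Methods

This note documents the models, parameter choices and numerical decisions
behind `tracemap`, and what the synthetic study conditions do and do not
establish about real tracing data.

## Injection-site extraction

**Wavelet band surgery.** Sections are min-max normalized to [0, 1] and
decomposed with `db4` (compactly supported, orthogonal — chosen so that an
unmodified pyramid reconstructs the image to < 1e-6, which is asserted as
an invariant) over 5 levels with symmetric reflection padding.  Detail
levels 1–3 (fiber-scale texture) are zeroed.  At levels 4–5, diagonal
coefficients with |C| above the 0.9 quantile are multiplied by 2.0 and
horizontal/vertical coefficients below the 0.5 quantile by 0.5; the
level-5 low-pass block is multiplied by 0.5 and smoothed with a Gaussian
(σ = 2 coefficient cells).  Quantile thresholds make "large" and "small"
scale-free across exposure settings; the gain/damp factors are exposed on
`BandModification`.  Only the level-5 low-pass block is touched, and all
modifications are multiplicative; additive variants were considered and
rejected as scale-dependent.

**Adaptive contrast.** The exponent field c = c₁(f_g + ε)/((1 − f_g) + ε) + c₂
uses c₁ = c₂ = 1, ε = 1e-3 and a σ = 8 px Gaussian for f_g.  ∂T/∂c =
(π²/4) f^c ln f is defined as 0 at f = 0 (its limit).  The divisor f_g is
floored at ε.  Output is min-max renormalized; `renormalize=False`
returns raw enhancement values.  A note on the Taylor form: the
small-angle amplitude sin u ≈ u agrees within 2% for u = (π/2)f^p with
f^p ≤ 0.2, but the *squared* maps differ by up to 3.4% at that boundary;
tests assert 2% on the amplitude and 4% on the squared maps.

**MSER.** Extremal regions are connected components of {image ≥ t} on an
8-bit quantization, restricted to the component-tree branch through the
global intensity maximum (the injection core is by construction the
brightest structure).  Stability q(t) = (area(t−Δ) − area(t+Δ))/area(t)
with Δ = 5; maximally stable thresholds are local minima of q with area
in [50 px, 25% of the raster].  Enhancement leaves a shallow intensity
ramp at the blob edge which produces a run of nearly equivalent local
minima, so candidates are grouped by a min-diversity factor (regions
within 80% of the largest candidate's area count as one scale) and the
most stable region at the largest scale is returned.  A blank or
structureless image yields an empty blob with a warning status rather
than an error.

## Domain demarcation

Coordinates are z-scored per level before the RBF kernel so the γ grid is
scale-free; grids default to C ∈ {2⁻²…2⁵} and γ ∈ {2⁻⁵…2²} (64 members).
"10 threefold cross-validation" is implemented as 10 independent repeats
of stratified 3-fold CV (30 held-out scores averaged per member), with
the fold sequence derived from the training seed and shared across
members.  Ties in the weighted vote break by the fixed class order
medial < lateral < caudal.  Levels are fully independent: no smoothing
across adjacent atlas levels.  Training requires at least two classes
with at least `cv_folds` points each; boundary maps are raster-valued
(no contour vectorization).

## Connectivity analysis

The rectangular injection × target matrix is treated as a weighted
bipartite graph and Newman modularity is maximized on it with Louvain
(networkx implementation), resolution γ = 1.0, 100 runs with independent
node-order seeds drawn from a root seed.  Threshold comparisons keep
entries *at* the threshold (0.0045 pixel density anterograde, 8 cells
retrograde).  Row normalization scales every nonzero row's total to the
maximum row total, preserving within-row proportions bit-exactly for the
maximal row.

**Consensus.** The co-assignment matrix of the runs is thresholded at
τ = 0.5 and reclustered with Louvain until all reclustering runs agree
(Lancichinetti–Fortunato style), then polished: each node moves to the
community with maximal mean co-assignment, ties resolving to the lower
community id, and nodes with no positive co-assignment staying put (this
keeps consensus of identical partitions exactly idempotent).  Community
ids are contiguous from 0 in sorted-node order, making consensus
deterministic under a fixed seed.

**Summaries.** Matrix reordering groups rows/columns by community id and
sorts within community by descending total strength, putting each
community's strongest connections on the diagonal.  Pixel color coding
assigns each segmented pixel to the injection with the greatest
annotation value at the pixel's grid cell *within that grid's consensus
community*; grids whose community lacks an injection are flagged and left
uncolored.  Grid cells are (level, row, col), row-major, 0-based, 175 px
square.  Stacked-bar data reports each injection's per-level labeling
fraction plus the two ROIs with the highest summed label per level.
Projection-vector clustering L1-normalizes per-case region totals and
uses cosine distances with average linkage (configurable; the linkage
method is a convention, not a derived choice).  Tertile binning sends
boundary ties to the stronger bin, so an all-equal input is uniformly
"strong".

## Morphometry

**Trimming** cuts each neurite at its first node whose Euclidean distance
from the soma centroid exceeds the radius (default 300 in the
morphology's native length units — the radius is deliberately unit-free,
since deposited reconstructions mix unit conventions); everything distal
is dropped, including portions that re-enter the ball.

**LOESS** fits a quadratic per coordinate against vertex rank along the
branch, over 5 neighbors on each side (shrinking near branch ends), with
tricube weights on rank distance; endpoints and bifurcations are
bit-identical to the input and all fits read input coordinates, so the
result is order-independent.  Collinear evenly spaced branches are exact
fixed points.

**Features** follow L-Measure-style conventions: tortuosity = mean branch
path/chord; partition asymmetry = mean |L − R|/(L + R − 2) over
bifurcations (0 when undefined); Rall's ratio = (r₁^1.5 + r₂^1.5)/r₀^1.5;
branch generation = max bifurcations on a root-to-tip path; fractal
dimension by box counting (grid of 4 box sizes spanning the arbor) on the
1-unit-resampled polyline; soma features (volume, area-derived
sphericity π^{1/3}(6V)^{2/3}/A, spherical diameter, extents, coordinate
and Euclidean skewness) come from the convex hull of the soma point
cloud, flagged missing for degenerate somata.  Sholl intersection counts
use the endpoint rule (an edge crosses a sphere when its endpoints
straddle the radius); the surface-area variant assigns each frustum's
lateral area to the bin of its midpoint path distance over the maximum
path distance, and bin sums conserve total area to 1e-9.

**Statistics.** Rank-sum tests use the Mann–Whitney U of the first
sample, exact null for small untied samples and the
continuity-corrected normal approximation otherwise (all-tied samples
give p = 1 exactly); Hodges–Lehmann shifts use the standard
order-statistic CI.  Benjamini–Hochberg runs jointly across the whole
feature × group-pair family.  PCA z-scores features and drops constant
columns with a warning.

**Persistence.** Diagrams use the path-distance-from-soma filtration with
the elder rule (the farthest-reaching branch survives each merge); one
point per terminal tip, root branch dying at 0.  Wasserstein distances
use the L∞ ground metric, order q = 1, diagonal projections at half the
persistence, and an exact assignment solve on the diagonal-augmented
cost matrix.

## Synthetic study conditions

The generators define the conditions everything is tested under:

* **Sections** are 256² rasters with a radius-25 blob (peak 0.95 over
  background 0.08), 2% fiber cover, and σ = 0.01 Gaussian noise.  Blobs
  are wobbled ellipses (three low-order angular harmonics) with
  multiplicative speckle clipped so the interior stays above half peak.
* **Domain clouds** are anisotropic Gaussians (axis ratio 1.5) truncated
  to an elongated nucleus-shaped polygon in a 160 × 120 frame, 500 points
  per domain.  A global covariance scale is calibrated by bisection so
  the expected fraction of points nearer a foreign center is the
  requested overlap (10% in the study conditions); zero overlap instead
  truncates each cloud to its own nearest-center cell.  Ground truth is
  the argmax of the truncation-corrected mixture densities — a
  likelihood-ratio boundary, which is also the Bayes rule the ensemble
  is implicitly estimating.
* **Matrices** are 40 injections × 400 grid targets in three blocks with
  lognormal within-block weights (CV 0.25) and off-block noise an order
  of magnitude weaker.
* **Neurons** draw their bifurcation count as Poisson with the
  branching-process mean n_stems·p/(1 − 2p), p = bifurcation_rate ×
  mean_branch_len, realized as a uniformly random recursive binary
  forest; branch lengths are Gamma (shape 6, mean 40), steps 2 units with
  von Mises–Fisher direction persistence whose concentration is
  calibrated (cached bisection against an internal Monte Carlo) to the
  tortuosity target, growth capped at 200 units from an ellipsoidal soma
  sampled as 40 surface points.  Drawing the count directly gives the
  Poisson-like seed-to-seed dispersion real reconstruction cohorts show;
  a live birth–death cascade at the same mean is heavy-tailed and was
  rejected for that reason.

What passing these conditions does *not* show: robustness to
registration error, tissue artifacts, multi-channel bleed-through,
uncalibrated background texture statistics, or real somato-dendritic
geometry; the generators make no attempt to match the intensity
statistics of any particular microscope.  Recovery results quantify the
pipeline's correctness on its stated model, not field performance.

## Problem sizes

Default verification runs use: 20 sections for blob recovery; 7 atlas
levels × 1500 training points with the full 64-member ensemble and a
9435-pixel mask per level for boundary agreement; 100 Louvain runs on the
40 × 400 matrix; 50 replicates of 10-vs-10 neuron cohorts (plus 50 null
replicates) for the FDR power/false-positive study.  These sizes were
chosen to keep each stage's check statistically meaningful while the
whole suite stays lightweight on a single CPU.
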