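# Methods

`exinemorph` quantifies the micro-ornamentation of grass (Poaceae) pollen
exine surfaces from high-magnification SEM crops and compares groups of
grains in the resulting morphospace. This note records the model, the
numerical choices, and what the synthetic studies do and do not demonstrate.

## The measurement model

The unit of analysis is a square grayscale crop of exine surface, nominally
1855 × 1855 px covering ~3.3 μm² at ×150 000 (≈0.98 nm/px). Each grain is
summarised by a 40-dimensional vector:

1. **log size** — mean length of detected surface objects, in pixels.
2. **log density** — count of bright surface elements (areolae/spinule
   clusters) per analysis window.
3. **SC2₁…SC2₁₉ and SC3₁…SC3₁₉** — connected-component counts of expanding
   top-ranked regions of a subgraph-centrality field, computed under two
   binarizations (top two vs top three brightness classes).

### Preprocessing

The crop is contrast-equalized and five 1000 × 1000 px windows are cut at
uniform-random offsets (with replacement; windows may overlap). Every
feature is measured per window and averaged over the five windows before
the log transform (mean-then-log). Per-grain sampling seeds derive from a
single run seed and the grain id by hashing, so grain order and parallelism
cannot change results.

Equalization is contrast-limited adaptive histogram equalization (CLAHE)
pulled toward a bell-shaped value distribution: scikit-image's CLAHE
(uniform target, clip-limited) followed by a global monotone Rayleigh
quantile map. The composition preserves CLAHE's local rank structure while
reshaping the overall histogram toward the Rayleigh bell; its parameters
(tile grid 8 × 8, clip limit 0.01, Rayleigh mode σ = 0.4) are configurable
and the defaults are conventional CLAHE settings, since the protocol names
the operation but not its parameters.

### Size

Objects are found by derivative-of-Gaussian Sobel edge detection
(pre-smoothing σ = 1 px), Otsu-thresholded on gradient magnitude,
hole-filled, eroded by one pixel, and labeled with 8-connectivity. The
one-pixel erosion matters: the Sobel ridge straddles the true contour, so
the filled object is dilated by about one pixel per side; erosion restores
the analytic calibration. Each object's length is 4·√λ₁ of its member-pixel
coordinate covariance — exactly the diameter for a uniform disc
(variance r²/4) and 1.1547·L for a uniform bar (variance L²/12). The window
size is the unweighted mean over objects at least 5 px in area; a window
with no object contributes nothing (the grain mean skips it), and a grain
with no measurable window is excluded as incomplete.

### Density

The window is lightly smoothed (Gaussian, σ = 1 px) and brightness-quantized
by 1-D k-means (weighted Lloyd on the unique-value histogram, quantile
initialization, ties to the lower class, hard iteration cap — fully
deterministic); the brightest class is taken as foreground, a morphological
closing with a 2-px disc fuses fragments, components under 5 px are
dropped, and the remaining 8-connected components are counted. The
pre-smoothing is the quantization-side counterpart of the
derivative-of-Gaussian edge choice: contrast equalization amplifies
background noise, and without it the class boundary occasionally falls
inside the noise mode and shatters the foreground into specks.

The density quantization depth defaults to **k = 3**, not the 4 classes the
SC features use. With four classes the brightest class flips between whole
element tops and just their spinule peaks depending on how much of the
window the elements cover, which makes the count jump by roughly a factor
of the spinule number between otherwise similar images; we confirmed the
flip is a property of the intensity distribution itself (an exact
dynamic-programming 1-D k-means reproduces it), not of Lloyd initialization.
At k = 3 the brightest class is the element tops — spinules included — in
every packing regime, and the count tracks the true element count. Both
depths are configuration keys (`density_kmeans_k`, `kmeans_k`).

### Subgraph-centrality features

Per window: anti-aliased resize 1000 → 200 px, center-crop 120 × 120,
quantize to four brightness classes, binarize by the top two (SC2) or top
three (SC3) classes, then block-reduce 120 → 40 (a 3 × 3 block is
foreground iff its mean ≥ 0.5, ties to foreground). The 40 × 40 tile
becomes a 4-neighbour lattice (3120 edges); edges crossing the
foreground/background boundary are attenuated to weight 0.01, all others
are 1. The subgraph centrality of pixel *i* is

    SC(i) = [exp(A)]ᵢᵢ = Σₖ (Aᵏ)ᵢᵢ / k!,

the weighted count of closed walks through the pixel; pixels deep inside
large foreground "chambers" rank high. All 1600 pixels are ranked by SC
(descending, raster-order tie-break) and, for k = 1…19, the top 80·k pixels
(5 % steps) form a nested region whose 4-connected component count is
feature k. The 19 steps stop at 95 % of pixels; the region at k would
saturate to a single trivial component at 100 %. Regions are nested, but
counts need not be monotone — a later shell can bridge earlier fragments.

The exponential is computed by scipy's dense matrix exponential
(~1.4 s per 1600-node lattice on one core); the test suite checks it
against an independent 30-term Taylor-series oracle to 10⁻⁸ relative error.
A degenerate mask (all foreground or all background, e.g. a constant
window) short-circuits to all-ones counts: the uniform lattice's SC field
carries only symmetric ties, so its "expanding regions" would be tie-break
artifacts.

## Morphospace analysis

PCA of the 40 features, by default on the correlation matrix — the features
mix log scales and integer counts, so unit variance is the defensible
default; covariance mode is retained as an option because published
variance fractions depend on this unstated convention. The sign of each
axis is fixed by making its largest-magnitude loading positive. In
correlation mode a zero-variance feature is an error naming the column
(matching R's `prcomp(scale = TRUE)`); `drop_constant=True` removes such
columns with a warning instead, which the CLI uses because saturated SC
counts (e.g. SC3₁₉ = 1 for every grain) are routinely constant in small
cohorts. Group
comparison uses:

* **50 % confidence ellipses** in the PC1 × PC2 plane, from each group's
  score mean and 2 × 2 covariance, boundary at Mahalanobis radius
  √χ²₂(0.5) ≈ 1.1774. Singular covariances are flagged degenerate rather
  than drawn.
* **Centroid Euclidean distances**, in raw 40-D feature space by default,
  with standardized-40-D and PC-score space as options (the last two are
  isometric when all components are kept, which the tests assert).
* **Loadings reports** ranking features by absolute loading per axis, and a
  convenience "density-dominated axis" (the PC with the largest |loading|
  on log density) used when asking whether cohorts order by ornament
  density.

A reproduction harness (`reproduction_report`, CLI `reproduce`) refits the
morphospace over the full grid of open conventions — correlation vs
covariance scaling, natural vs base-10 log of size/density, feature-space
vs score-space distances — against externally supplied reference
statistics, and flags the best-matching configuration. No reference values
are baked into the package; they are user input.

## Synthetic textures

The generator emulates areolate/spinulate ornamentation: flat-topped bright
discs ("areolae") on a jittered hexagonal lattice, separated by darker
channels, edges softened by Gaussian blur so gradient detection behaves as
on real texture, studded with small brighter peaks ("spinules"), plus
Gaussian imaging noise, all clipped to [0, 1] and fully seed-deterministic.
The hexagonal placement guarantees the channels and packing feasibility
that Poisson placement does not; requests covering more than 80 % of the
frame are rejected.

Defaults emulate a 1855-px crop: ~40 areolae of radius 90 px (~180 nm
diameter at the nominal pixel pitch) separated by 30-px channels, four
spinules of radius 12 px each, noise σ = 0.05, background/element/spinule
intensity 0.25/0.70/0.95. Simulation studies run at reduced 512-px frames
with proportionally scaled radii (radius 18 ± 4 px, channels 8 px,
spinules 3 × 3.5 px) and 256-px analysis windows, which keeps a 30-grain
cohort study to a few minutes on one core; the smaller frames preserve the
element-to-window scale ratio of the nominal protocol.

Two stock study designs cover the two questions the synthetic cohorts
answer. The *recovery set* (`recovery_set_spec`, 30 grains) spreads element
counts evenly over 20–80 and radii independently over 14–22 px (both on
shuffled grids, so rank correlations are not weakened by ties or
count–radius confounding); it asks whether the features recover the
generator's parameters. The *scenario cohort* (`study_cohort_spec`,
3 × 10 grains) has element-count means 60/40/25 with equal within-group
parameter variance (±10 counts, ±4 px radius) — decreasing ornament
density with constant within-group spread, a pure morphospace *location*
shift. The tests assert the pipeline sees it as such: group centroids
order monotonically along the density-dominated axis — the PC most
*correlated* with log density, i.e. largest |loading| × √(explained
fraction), since a raw-loading argmax picks near-noise late components —
and PC1 × PC2 ellipse areas stay within a factor of two.

Extent comparisons at low density carry an intrinsic caveat: the measured
within-group scatter includes window-sampling noise that grows as element
counts shrink (the 120 × 120 SC tile holds only a couple of elements at
count 25), so the sparsest group's measured extent is partly measurement
noise rather than parameter spread. Equalizing *relative* parameter jitter
does not help — it shrinks the dense groups' spread without touching the
sparse group's noise floor — which is why the design uses equal absolute
parameter variance.

**What passing these tests does not show:** the generator has uniform
illumination, isotropic circular elements, and stationary noise. Real SEM
crops have curvature shading, charging gradients, non-circular and fused
areolae, and depth-of-field blur. The synthetic studies validate the
mechanics and the sensitivity of the feature chain, not its calibration on
real exine texture; absolute size/density values on real material should be
interpreted relative to within-study comparisons.

## Numerical and degenerate-input choices

* Intensity normalization divides by the dtype maximum, preserving absolute
  brightness across grains; images under 1000 px (configurable) are
  rejected at load time.
* Quantization with fewer distinct intensities than classes merges the
  empty classes with a warning; a constant window yields density 0,
  size NaN, and the all-ones SC fallback.
* Component labeling is 8-connected for object work at window scale
  (standard blob counting) and 4-connected inside the SC features, matching
  the 4-neighbour lattice.
* Sub-image sampling is with replacement over offsets; the protocol's
  "randomly chosen" gives no exclusion rule, and overlap is harmless to
  averaged features.
* Equalization precedes window sampling (the textual order of the
  protocol); both orders are trivially recomposable from the library
  functions if needed.
* Feature tables are written with 17 significant digits; round-trips are
  lossless at double precision and byte-stable across repeated writes.

## Known limitations

* The SC step cost is ~1.4 s per window-binarization (two per window); a
  1000-grain study is hours of single-core compute. A Lanczos or
  polynomial-approximation path for diag(exp(A)) would cut this by an
  order of magnitude but is deliberately out of scope.
* The 50 % ellipses are bivariate normal summaries; heavy-tailed or curved
  group scatters will be summarised poorly (the coverage test holds for
  Gaussian scores only).
* Size calibration (the 4·√λ₁ rule) is exact for convex, uniformly filled
  objects; strongly concave fused areolae bias it upward.
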