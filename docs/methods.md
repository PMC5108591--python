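# Methods

`myoquant` quantifies myogenic differentiation assays from multi-channel
fluorescence micrographs and fits the statistical models those assays
require.  Because raw experimental images for this class of assay are
rarely deposited, the package is built around a synthetic-scene
generator with exact ground truth: every downstream layer is validated
by recovering known generating parameters.  This note documents the
models, the defaults and the design choices.

## Synthetic scenes

A scene is a field of view (default 768 × 768 px, 16-bit) containing
two cell populations:

* **Myoblasts** — mononucleated elliptical cells.  Eccentricity
  e = √(1 − (b/a)²) is drawn from a normal distribution (default mean
  0.6, SD 0.1, truncated to [0, 0.93]); the semi-axes preserve a
  constant geometric-mean radius (default 16 px, ≈ a 30 µm cell at
  1 µm/px), so elongation does not change area.  Each holds one
  nucleus (disk, radius 6 px) near its centre.
* **Myotubes** — multinucleated capsules (rectangle with semicircular
  caps) at least four times longer than wide, holding k nuclei spaced
  along the major axis.  k is drawn over the size classes
  {2–4, 5–9, 10–24, ≥25} with default weights (0.45, 0.30, 0.20, 0.05)
  and capped at 40 for rendering.  The shape is a modelling choice:
  the literature describes myotubes qualitatively ("elongated,
  multinucleated"), not numerically; the capsule exercises both
  nucleus assignment and size classification.

Two fusion parameterisations are available.  With `myotube_fraction`,
each cell is independently a myotube with that probability.  With
`fusion_probability`, each of a fixed pool of nuclei fuses
independently with probability p and fused nuclei are grouped into
myotubes; the scene's true fusion index is then an exact Binomial(N, p)
draw, which gives the dose–response benchmark an exactly known
logistic truth.  (If exactly one nucleus fuses it is demoted to a
myoblast — a myotube needs two — which perturbs p by O(1/N).)

Cells are placed by rejection sampling with a 3-px clearance between
outlines (1000 attempts per cell; failure raises an error naming the
achieved count).  Placement forbids overlap; the segregation of
*overlapping* cytoplasm is still exercised by constructed fixtures in
the test suite.  Rendering adds, in order: per-cell intensity jitter
(±10%), a smooth low-frequency cosine background (relative amplitude
0.3 of the cytoplasm level by default), saturated speckle artifacts
(3–9 px diameter, 5 per megapixel per channel), and additive Gaussian
noise (SD 0.02 of full scale).  A marker named `myhc` is forced
positive on myotubes (myotubes are MyHC⁺ by definition of the assay)
and Bernoulli on myoblasts.

Randomness is split into sub-streams derived from the scene seed
(geometry = 0, markers = 1, rendering/noise = 2), so changing the
noise level never moves a cell.

What the generator does *not* emulate: point-spread-function optics,
chromatic aberration, uneven illumination beyond a single smooth
gradient, 3-D structure, cell debris, or segmentation-hostile clumping.
Passing the recovery benchmarks therefore shows the pipeline is
correct under its stated assumptions, not that it is robust to every
failure mode of real micrographs.

## Segmentation

1. **Band-pass pre-processing.**  The background is estimated by a
   Gaussian at scale `low_sigma` (default 50 px, large relative to
   cells) and subtracted with clipping at zero.  Bright compact
   artifacts are then removed: connected components above the
   `artifact_min_intensity` quantile (default 0.999) with area below
   `artifact_max_area` (default 100 px²) and solidity above 0.9 are
   zeroed (with a 1-px dilation) — *provided they are isolated*, i.e.
   the rim around the component lies mostly on background rather than
   inside a larger stained object.  The isolation test is what lets
   the rule remove saturated speckles without punching holes into
   bright nuclei, whose brightest pixels also reach the top quantile.
   All cutoffs are engineering defaults exposed in
   `SegmentationConfig`.
2. **Nucleus detection.**  Otsu threshold, watershed split of touching
   nuclei on the Euclidean distance transform (peak separation
   7 px), removal of components below 40 px², labels renumbered in
   raster-scan order of each component's first pixel.  An empty mask
   warns and returns zero labels rather than raising.
3. **Cell segregation.**  Two conventions, selected by `cell_mode`:
   * `"component"` (default): a cell is one connected cytoplasm
     object.  This is the convention the fusion index and size-class
     assays require — a myotube is a single object containing many
     nuclei.  Nucleus-free components are dropped.
   * `"voronoi"`: every cytoplasm pixel is assigned to the
     geodesically nearest nucleus *within the cytoplasm mask*
     (multi-source Dijkstra on the 8-connected pixel graph, axial
     steps 1, diagonal √2), splitting touching cells along the
     equidistant ridge while never bridging background gaps.  Exact
     distance ties resolve to the lower nucleus label via per-label
     virtual source nodes.  This is the convention for scoring
     per-cell shape in dense monolayers of mononucleated cells, where
     touching neighbours must be separated.
4. **Shape.**  Eccentricity from second-order central moments of the
   pixel coordinates: with λ₁ ≥ λ₂ the covariance eigenvalues,
   e = √(1 − λ₂/λ₁); 0 for a disk, → 1 for a line.  Note the
   direction: *larger = more elongated*.  Some texts describe the same
   scale inverted (circle = 1, line = 0); the monotone inversion does
   not change which condition is "more elongated", and this package
   uses the standard moments convention throughout.  Regions under
   5 px or collinear raise an error.  Rasterization keeps the measure
   within 0.02 of the analytic ellipse value for semi-minor axes
   ≥ 10 px; rotation and translation invariance hold to the same
   tolerance.
5. **Summaries.**  The frame score is the unweighted mean eccentricity
   over retained cells; cells touching the frame border are excluded
   by default (configurable).  Nuclei are counted per cell by the cell
   label under each nucleus centroid (majority fallback), with
   unassigned nuclei tracked so that per-cell counts plus unassigned
   always equal the detection total.  Marker positivity is the mean
   in-cell marker intensity against an Otsu threshold over per-cell
   means (or a fixed value).

## Assay metrics

* **Fusion index** = (nuclei in MyHC⁺ cells with ≥ 2 nuclei) / (all
  nuclei in the field of view).  A gated variant restricts the
  numerator to cells also positive for a second marker (e.g.
  eGFP⁺/MyHC⁺ in transduction experiments) while keeping all nuclei in
  the denominator; the denominator convention is a config switch.
  Raw counts are retained for binomial modelling.
* **Size classes**: small 2–4, medium 5–9, large 10–24, very large
  ≥ 25 nuclei — inclusive bounds forming an exact partition.
  Mononucleated MyHC⁺ cells are never myotubes (the ≥ 2 rule is
  applied uniformly).
* **Marker fractions**: k/n with optional gating; an empty gate yields
  a missing value with a warning, not an error.
* **Engraftment**: per-section counts of donor (LAMIN A/C⁺) nuclei
  inside/outside host fibres and donor-derived (SPECTRIN⁺) fibres,
  summarised as totals per muscle, means per section, and the profile
  along the muscle (sections are cut at a fixed spacing, e.g. 112 µm).

## Statistical models

All fits are implemented in this package; statsmodels and lme4 appear
only as independent cross-checks in the test suite.

* **Binomial logistic GLM** (grouped or Bernoulli): IRLS to the
  maximum-likelihood estimates, convergence at max |Δβ| < 1e-10 within
  100 iterations, covariance from the inverse Fisher information.
  Grouped and fully expanded representations give identical
  coefficients.  Diverging coefficients (|β| > 30 on the logit scale)
  raise an explicit separation error.
* **Quasi-Poisson**: log-link IRLS with Poisson weights; dispersion
  φ = Pearson X²/(n − p); SEs scaled by √φ; p-values from a t
  distribution on n − p df.
* **Linear models**: OLS with t-based approximate p-values (used for
  per-frame eccentricity dose models).
* **Binomial GLMM** (random intercept): marginal likelihood by
  *adaptive* Gauss–Hermite quadrature (default 25 nodes; nodes centred
  at each group's posterior mode, scaled by the curvature there),
  maximised over (β, log σ_g) with L-BFGS-B.  Adaptive quadrature was
  chosen over penalised quasi-likelihood because PQL is biased for
  binary data with few groups.  Rows sharing a group and covariate
  pattern are aggregated first, which leaves the likelihood unchanged
  and makes per-cell tables cheap.  σ_g is optimised on the log scale;
  fits at the σ_g → 0 boundary (σ_g² < 1e-8, or marginal likelihood
  indistinguishable from the fixed-effects limit) collapse to the
  plain GLM.  Fixed-effect covariance comes from the central-difference
  Hessian of the marginal log-likelihood; the reported log-likelihood
  includes the binomial normalising constants (lme4's `glmer` reports
  it relative to the saturated model — subtract that constant when
  comparing).
* **Design matrices** are treatment-coded with a fixed column order —
  intercept, main effects, interactions, dose (linear in
  concentration), batch dummies — and rank-checked by pivoted QR, with
  aliased columns named in the error.
* **Effect reports**: Wald z (or t) per term; odds/rate ratios
  exp(β̂) with 95% intervals exp(β̂ ± 1.96·SE).  Per-condition fitted
  values use the delta method on the summed coefficients; a flag
  reproduces the reporting convention in which the intercept's error
  contribution is omitted from treatment-condition intervals (the
  baseline row keeps its full variance — the intercept is its only
  term).  Note this "narrower interval" behaviour holds when the
  intercept–effect covariance is non-negative; with the usual negative
  covariance of treatment coding the flagged interval can be wider.
  Wald rather than profile intervals match the ± SE convention of
  tabulated summaries.  No multiple-testing correction is applied;
  p-values are reported per model.

## Benchmarks and problem sizes

`myoquant.validation` regenerates every benchmark from scratch (all
stochastic ones take explicit seeds): 40 rasterized ellipses for the
eccentricity oracle; 20 scenes of 100 cells (background 0.3,
5 speckles/Mpx) for segmentation truth recovery; closed-form saturated
fits; 10 random problems against statsmodels; 50 replicates of
10 groups × 500 cells for GLMM recovery; 2,000 null simulations at
n = 100/cell for interaction-test calibration; an exhaustive
size-class partition check; and a 24-scene dose series
(4 doses × 3 groups × 2 frames, 150 nuclei per scene) through the full
pipeline.  These sizes are chosen so the complete report runs in about
a minute on a laptop core while leaving each stochastic check enough
resolution for its stated tolerance.

## Known limitations

* Physical pixel size is configurable but uncalibrated by default;
  all geometry is in pixels.
* One scalar random intercept only — no crossed or nested random
  effects; no Bayesian fitting; no survival models.
* `"component"` mode cannot separate genuinely touching cells (use
  `"voronoi"`), and `"voronoi"` mode dismembers myotubes (use
  `"component"`): the choice encodes which assay is being run.
* The marker threshold (Otsu over per-cell means) assumes both
  positive and negative cells are present in a frame.
* Segmentation is classical; no learned models, 3-D, deconvolution or
  tracking.
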