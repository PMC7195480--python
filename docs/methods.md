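# Methods

## Calibration model

The sensor's ratio–concentration relation is modelled as a Hill sigmoid
R(C) = Rmin + (Rmax − Rmin)·Cⁿ/(K′dⁿ + Cⁿ), with the apparent dissociation
constant K′d in µM and dimensionless Hill coefficient n. The inverse
(ratio → concentration) is the standard ratiometric equation
[Ca²⁺] = K′d·((R − Rmin)/(Rmax − R))^(1/n). Concentrations are stored in µM
internally and reported in nM (fixed factor 1000), matching the convention
of in-vivo mitochondrial Ca²⁺ work.

Fitting uses Levenberg–Marquardt least squares with K′d and n parameterised
on the log scale to enforce positivity. Initialisation is deterministic:
Rmin/Rmax from the observed ratio extremes, K′d from the concentration
whose ratio is nearest the ratio midpoint, n = 1. At least 5 titration rows
are required; all-equal ratios, non-positive ratios, or a non-increasing
concentration grid are rejected with a named precondition error.
Diagnostics (RMS residual, per-parameter standard errors from the Jacobian)
travel with the fitted curve.

**Out-of-range ratios.** Under noise a measured ratio can fall at or outside
(Rmin, Rmax), where the inverse equation is undefined or infinite. Such
ratios convert to NaN and are counted in a QC report rather than clipped;
clipping would silently fabricate 0 or ∞ concentrations. R = Rmin maps to
exactly 0 nM.

The default curve constants are Rmin = 0.606, Rmax = 2.6921, K′d = 4.21 µM,
n = 1.57 (in-situ calibration of the mitochondria-targeted YC3.6 sensor in
neuroblastoma cells); the 13-point titration design spans 0–1000 µM.

## Image processing

Processing order is fixed: background subtraction → smoothing →
segmentation → ratio measurement.

- **Background**: per channel and per z-slice, the mean of the lowest 5% of
  the slice's intensities is subtracted and negatives are clamped to zero.
  The subtracted offsets are returned as a QC table. On noisy data the
  bottom-5% mean underestimates the true offset by ~2σ of the read noise;
  this bias cancels in the ratio (it affects both channels equally) and is
  small relative to object signal.
- **Smoothing**: per-slice 2D mean filter, radius 2, square (2r+1)² kernel
  by default (a digital disk is available via config). Smoothing assists
  segmentation only; ratios are measured on unsmoothed channels by default
  because averaging across an object's boundary mixes object and background
  photons (the smoothed alternative is exposed as a config option).
- **Segmentation channel**: the CFP+YFP sum. Under the ratiometric forward
  model the sum is independent of Ca²⁺, so detection is unbiased with
  respect to an object's Ca²⁺ level, which single-channel detection would
  not be.
- **Adaptive threshold**: per-slice local mean over an odd `block_size`
  window (default 51 px), plus a configurable additive `offset` (default 0),
  plus a **noise floor** of `noise_k` (default 3.5) times the slice's robust
  noise scale (1.4826·MAD). The noise floor is this package's design choice:
  a pure local-mean rule marks ~half of all background pixels on any noisy
  image, which percolates under 26-connectivity into one stack-wide
  component. Because the MAD term is zero on noise-free data and scales
  linearly with intensity, the rule degrades to plain local-mean
  thresholding in the clean limit and the binary mask is invariant to
  multiplying both channels by a common positive factor.
- **Labelling**: 3D connected components (26-connectivity by default), with
  physical size bounds (defaults 0.2–500 µm³) converted to voxels via the
  stack's voxel size. Labels are renumbered contiguously.
- **Compartments**: objects larger than 20 µm³ (configurable), or touching a
  user-supplied soma mask, are tagged "soma"; the rest "neurite". The rule
  is an explicit, overridable heuristic.
- **Plaques**: manually supplied masks are used as-is; alternatively the
  plaque-label (RED) channel is thresholded (Otsu unless given) with a
  50 µm³ speck floor. A plaque's *edge* is the set of mask voxels 6-adjacent
  to background.

## Quantification and statistics

- Per-object ratio = Σ(YFP voxels)/Σ(CFP voxels) over the object's voxel
  set; concentration via the calibration curve. Zero CFP sum gives a missing
  ratio and a QC flag.
- Volume summaries are unweighted means over objects (each mitochondrion
  counts once); voxel-weighted means are available via an option.
- The overload threshold is control mean + 2·sample SD (ddof = 1) over all
  pooled control objects; classification uses strict ">". The responder cut
  for treatment effects uses "≥ 5%" on ΔR/R₀ = 100·(R_after − R_before)/R_before.
- Distance to plaque is the minimum Euclidean distance (anisotropy-aware µm)
  from the 3D object centroid to any plaque edge-voxel centre, 0 inside a
  plaque. Overload vs. distance uses contiguous [0,10), [10,20) … bins to
  100 µm by default; the bin comparison uses the Kruskal–Wallis rank test
  (tie-corrected H, chi-square reference). All-tied data returns H = 0,
  p = 1 by convention.
- Morphology is 2D per selected slice: area = pixel count·px², perimeter by
  either the literal boundary-pixel count (default; matches the historical
  hand-ROI convention but overestimates diagonal and underestimates tiny
  boundaries) or a Crofton-formula estimator that converges to true
  perimeters of smooth shapes. Circularity = P²/(4πA), exactly 1 for a
  continuous circle, 4/π for a square; larger = less circular. Objects with
  ≤ 2 boundary pixels are flagged below-resolution. Analysis slices are
  drawn from the 30–60 µm depth window with a seeded sampler
  (100–125 objects typical).
- Longitudinal matching is greedy ascending-distance nearest-centroid
  within a radius (default 10 µm for somata), deterministic index
  tie-breaking, each follow-up object used once; an optimal-assignment mode
  (Hungarian) is available. Unmatched baseline objects are DISAPPEARED.
  Survival vs. baseline ratio reports the 2×2 table at a ratio cut (default
  1.4) and a two-sample Student t-test between remained/disappeared
  baseline ratios.
- Cohort comparisons use a linear mixed model with treatment group fixed
  and a random intercept per mouse, fitted by REML (statsmodels MixedLM).
  p-values use a t reference with df = n_mice − n_groups — the exact
  between-cluster df for balanced designs and a conservative small-sample
  stand-in for Satterthwaite df, which the backend does not provide. At the
  var_mouse = 0 boundary, where REML can fail numerically, the model
  reduces analytically to OLS and that reduction is used. A mouse-level
  cluster bootstrap (percentile CI of the difference of group means of
  per-mouse means) provides a nonparametric cross-check. Groups represented
  by a single mouse are rejected. Significance threshold 0.05.

## Synthetic data

The generator emulates the structure of two-photon cameleon imaging:
ellipsoidal objects (small elongated "neurites", larger "somatic clusters")
with per-object total intensity I and true ratio R encoded as
CFP = I/(1+R), YFP = I·R/(1+R); per-slice additive background offsets
(base 20 counts, ±30% slice-to-slice); Poisson shot noise on the pre-offset
signal and Gaussian read noise (σ = 2); spherical plaques in a third
channel. All generators are pure functions of (spec, seed) and serialise
their ground truth (geometry, true ratios, per-slice offsets, labels) to
JSON.

Default stack geometry is 12 slices × 512² pixels at (1.5, 0.125, 0.125) µm
voxels with 50 objects: neurite-like objects 2.2–3.0 µm across and somatic
clusters 5–7 µm. The in-plane sampling is finer, and the neuritic objects
fatter, than the smallest real mitochondria: a radius-2 mean filter dilates
binary masks by ~2 px, so voxel-level IoU scoring against ground truth is
only meaningful for objects ≳ 18 px across. This scale was chosen once, as
the regime where overlap-based recovery benchmarks are informative; it
means the benchmarks certify the pipeline's geometry handling, not its
behaviour on objects at or below the optical resolution limit. Other real
features deliberately not modelled: the microscope PSF, depth-dependent
attenuation and scattering, motion, and spectral bleed-through — passing
recovery tests therefore demonstrates algorithmic correctness on idealised
optics, not end-to-end accuracy on tissue data.

Cohort presets: the control ("wt_like") object-ratio distribution is
N(0.67, 0.16²), whose mean + 2 SD is 0.99 — echoing the control anchors of
the in-vivo study design. The "tg_like" preset is a 95/5 mixture with a
high-Ca²⁺ component N(1.2, 0.1²) (analytic overload exceedance ≈ 7.1% at
threshold 0.99). These are generator settings for demos and recovery tests;
they are not claims of reproducing animal data, whose cohort-level numbers
require in-vivo data and are out of desk-scale reach.

Time-lapse shapes: depolarisation-like step with exponential approach,
slow monotone rise (oligomer-exposure-like), and exponential decay (for
membrane-potential / pore-opening / caspase-style normalised traces).
Longitudinal sessions pair a baseline with a follow-up in which every cell
above the ratio cut 1.4 disappears (deterministic rule) and survivors are
re-observed with 1 µm centroid jitter.

## Numerical choices and degenerate inputs

- Conversions: R = Rmin → 0 nM exactly; the ratio midpoint maps exactly to
  K′d (the Hill bracket equals 1). Round-trip ratio→conc→ratio is tested to
  1e-9 relative error.
- The adaptive threshold carries a `signal > 0` guard absorbing float
  round-off of the local-mean filter on empty regions.
- Sample SD exactly zero (all-equal control ratios) produces a degenerate
  threshold with a warning rather than an error.
- Greedy matching breaks distance ties by (baseline, follow-up) index order,
  making results order-deterministic.
- Monte-Carlo test sizes: 200 replicate noisy calibration fits, 10⁴-object
  overload pools, 500-replicate mixed-model recovery and 1000-replicate
  null simulations, 50-object segmentation stacks — sizes at which the
  checked tolerances are several standard errors wide while the full suite
  remains quick to run.

## Known limitations

- The boundary-pixel perimeter convention biases circularity low for
  objects a few pixels across (a 1-px object scores 1/(4π)); such records
  are flagged rather than suppressed.
- Morphology ROIs come from the segmentation masks; hand-drawn ROIs of the
  original workflow may differ systematically near object boundaries.
- Distances are straight-line 3D; geodesic (tissue-constrained) distances
  are out of scope.
- The mixed model treats the caller-chosen response (volume means,
  overload %, ΔR/R₀) as the residual unit; object-level responses within
  volumes would need an additional variance component that is not modelled.
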