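# Methods

This note documents the models, parameters and design choices behind
`cortexshift`, and what its synthetic validation does and does not show.

## Measurement model

All longitudinal change is expressed per vertex as a log2 follow-up/baseline
ratio: thickness `ΔCT = log2(CT₂/CT₁)`, surface area `ΔSA = log2(SA₂/SA₁)`,
volume `ΔV = ΔCT + ΔSA`.  Working in log2 makes volume change *exactly*
additive in its two components, which the code asserts bitwise.  Reported
"percent loss" is `(baseline − follow-up)/baseline × 100`, so the three
losses satisfy `(1 − v/100) = (1 − t/100)(1 − a/100)`.

Vertex area follows the one-third-triangle attribution rule: each vertex
owns a third of every incident triangle, so vertex areas sum exactly to
the mesh surface area (asserted to 1e-12 relative).  Global summaries use
the unweighted vertex mean for thickness (an area-weighted option exists
but is not the default — the convention matches how cortical means are
usually reported) and the vertex-area sum for area; global volume is their
product.

Thickness maps are smoothed per timepoint with a truncated geodesic
Gaussian (FWHM 20 mm, truncation 3σ, σ = FWHM/2√(2 ln 2)) before the
ratio; smoothing the log-ratio instead is available as an option.  The
kernel uses graph-geodesic distances (Dijkstra over mesh edges) with
per-vertex weight normalization, so constants are preserved exactly and a
maximum principle holds; graph distances slightly overestimate true
geodesics, which is immaterial at FWHM ≫ edge length.  Area change enters
volume unsmoothed.  The medial wall — one designated parcel of the
20-parcel icosahedron-face parcellation that stands in for a gyral
atlas — is excluded from every statistic.

## Registration

Each timepoint is a triangle mesh plus a spherical parameterization of the
same topology.  A coarse-to-fine series of control grids (icosphere levels
2…data_level−1, i.e. 162/642 control points for a 2,562-vertex data grid)
deforms the input sphere.  The warp at a data vertex is the normalized
barycentric blend of its three enclosing control points; each optimization
pass moves control points along six tangent directions with a shrinking
step (start 0.4 × control edge, four halvings), accepting only moves that
lower

  mean squared mismatch of the similarity feature
  + λ · (strain energy of the warp per unit area).

The similarity feature is z-scored radial deviation from the best-fit
sphere (a sulcal-depth proxy).  A curvature channel
(`compute_feature_channels`) exists but is not used by default: on
regridded surfaces, resampling-induced high-frequency differences make it
chase phantom mismatch.

The strain density per face uses the principal stretches of the in-plane
affine map, `W = c_shear(R/2 − 1) + c_bulk(J + 1/J − 2)` — non-negative,
zero exactly at an isometry, rigid-motion invariant, symmetric in
J ↔ 1/J for pure dilation.  Two design choices matter:

* **What is penalized.**  The regularizer measures the strain of the
  *warp increment*: the current anatomical image triangles relative to the
  image at the start of the control level.  Penalizing the whole
  baseline→follow-up deformation instead (which contains the biological
  change) measurably attenuates true atrophy — in development the
  recovered maps regressed on truth with slope 0.2–0.4.  With the
  warp-increment form the slope is ≈0.9.  The public `strain_energy`
  function still computes the full between-surface deformation energy,
  which is the quantity of diagnostic interest.
* **Where it is measured.**  In `anatomical` mode the image triangles live
  on the reference anatomy (the defining idea of anatomically constrained
  matching); in `spherical` mode the same warp strain is measured on the
  sphere.  On mildly folded surfaces with a near-uniform parameterization
  the two modes perform identically; with deep folds, a strongly distorted
  (inflation-like) parameterization and independent sphere misalignment,
  the anatomical metric is the more faithful prior and recovers truth with
  a lower error (asserted in the test suite under bumpiness 0.28,
  parameterization distortion 0.012 rad, drift 0.01 rad).

Defaults: `c_shear = c_bulk = 1`, `λ = 1.0`, tolerance 1e-4 relative
objective decrease per pass, ≤100 passes per level.  Accepted moves never
increase the objective; moves that would fold a spherical triangle are
rejected through a large orientation penalty.  Registration runs in both
directions; the reverse map is pulled onto the baseline grid through the
forward correspondence, negated, and averaged with the forward map.  This
cancels the systematic chordal bias of piecewise-linear surface images
(each direction alone underestimates image areas over curved regions).
The control grid stays one subdivision level coarser than the data grid —
the same 1:4 ratio as a 10,242-point control grid against a 32k data
mesh — because a control grid at data resolution injects per-vertex area
noise.

Per-vertex log2 area change from a correspondence maps each baseline
triangle onto the reference anatomy (barycentric interpolation of
reference vertex positions) and applies the one-third attribution rule to
baseline and image areas.

## Synthetic data

The generator emulates what matters for validating this pipeline, not MRI
physics:

* **Anatomy**: an icosphere (V = 10·4^level + 2; level 5 gives the
  10,242-vertex analysis resolution) deformed radially by a band-limited
  random field (spherical-harmonic degrees 4–min(14, 2^level); the cap
  keeps ≥ ~4.5 vertices per fold wavelength so coarse grids do not alias).
  Default radius 80 mm and peak fold amplitude 0.15 × radius give a
  hemisphere-like ~86,000 mm² surface.  The parameterization is mildly
  non-uniform (param points displaced 0.003 rad along the fold gradient,
  ±0.25 log2 areal distortion), emulating inflation distortion; it is a
  deterministic function of the anatomy, hence shared by the two
  timepoints.
* **Atrophy**: a global scale and/or two broad angular caps
  (temporal/parietal analogs, radii 0.72/0.55 rad, cos² taper) that
  contract the anatomy toward the cap centre.  A prescribed area-change
  field is not generally integrable, so the ground truth is *measured*
  from the known one-to-one correspondence after deforming — exact by
  construction, and `ΔV_true = ΔSA_true + ΔCT_true` holds bitwise.
  Default peaks per two-year interval at effect scale 1 (the AD analog):
  thickness −0.20 log2 (≈13%), area −0.09 log2 (≈6%), giving global mean
  area loss of ~1–2%.  These are order-of-magnitude choices, not
  literature rates; thinning is set to dominate volume loss, as it does
  in aging and dementia, which also makes the thickness and area map
  signal-to-noise ratios comparable — the regime in which volume is the
  most sensitive detection metric.  Group scales: CN 0, MCI-S ⅓, MCI-C ⅔,
  AD 1, times a lognormal subject factor (σ_log = 0.3).
* **Noise**: per-scan smooth correlated fields (not i.i.d. vertex noise —
  segmentation error is spatially coherent): displacement SD 0.03 mm per
  component and thickness SD 0.12 mm at correlation length 10 mm for the
  "3T-like" preset; the "1.5T-like" preset doubles both SDs.  The
  displacement SD corresponds to ~1% local areal strain per scan, chosen
  so that area is the stably measurable quantity (larger values make even
  oracle-correspondence area maps noise-dominated).
* **Regridding**: the follow-up is resampled at a rotated (0.05 rad) and
  smoothly jittered (0.02 rad) icosphere grid, so the two timepoints share
  no vertex set.  Resampling preserves total area exactly (a global
  rescale removes the ~0.2% shrinkage of piecewise-linear interpolation,
  which would otherwise masquerade as atrophy) and uses a
  gradient-augmented radial interpolation to avoid flattening folds.  An
  optional `drift_angle` misaligns the parameterization from the anatomy,
  emulating independent sphere inflations; it defaults to 0 (the
  generator's contract is that the identity parameterization is the true
  correspondence), and is switched on in the registration stress tests.

What the generator does **not** emulate: real sulcal geometry (folds are
radial, surfaces star-shaped), MRI intensities and segmentation,
demographic covariates, hemispheric asymmetry, and the true noise spectrum
of FreeSurfer reconstructions.  The cap contraction also redistributes
surface area toward the patch rim rather than removing it, so group
structure in *global* area loss is much weaker than in real dementia
cohorts — global-level group tests are exercised mainly through thickness
and volume.  Passing tests therefore show that the
measurement chain is correct and well-calibrated under known ground truth
and realistic noise magnitudes — not that effect sizes on real cohorts
will match.

## Inference

TFCE uses `H = 2, E = 1` (the surface-data convention), 100 integration
steps by default (`dh` = map maximum / steps), edge connectivity, and
vertex-area-weighted extent; positive and negative tails are enhanced
separately.  The implementation sweeps thresholds from high to low with a
union-find structure (numba-compiled), and matches an explicit
per-threshold connected-component integration to machine precision.

Permutation FWE: one-sample tests sign-flip subject maps (exhaustive when
2ⁿ ≤ 4096), group tests permute labels (exhaustive when the assignment
count is ≤ 10,000); the identity permutation is always included, so
corrected p-values never fall below 1/(P+1), and schemes with fewer than
20 distinct permutations are refused.  Default 1,000 random permutations
(500 in the experiment suite).  Tails: within-group atrophy is tested
one-sided (loss < 0), pairwise contrasts two-sided, F inherently
one-sided; all configurable.  The FWE family is the set of cortex vertices
of the supplied maps.  On zero-effect cohorts (n = 12 + 12, 500
permutations, 200 replicates) the family-wise rejection rate at α = 0.05
falls inside the binomial 95% band — the calibration uses
known-correspondence change maps, since only their exchangeability is at
stake and registering 4,800 null subjects would add nothing.

Global ANOVA uses scipy; Tukey HSD the studentized-range implementation in
`scipy.stats.tukey_hsd`; Cohen's d the pooled-SD form.  ROI MANOVA uses
statsmodels (Pillai's trace, cross-checked in the tests against an
eigenvalue computation), with an automatic highest-variance ROI-subset
reduction when subjects < ROIs + groups, and Bonferroni correction over
ROI × pair × metric tests.

## Experiments and problem sizes

The robustness experiments run at level 3 (642 vertices), where a
bidirectional registration takes ~1 s: the field-strength analog
regenerates 8 subjects with identical atrophy under both noise presets and
correlates their change maps; the sample-size analog registers one
90-subject cohort of the weak-effect MCI-S analog under 1.5T-like noise
once, then draws nested subsets (12 ⊂ 24 ⊂ 48 ⊂ 90, 8 replicates) and
runs the one-sample test per metric.  Power is defined at the map level
(any FWE-significant vertex inside the region of true area loss
> 0.02 log2); false positives count hits more than 26 mm outside the full
effect support (the 20 mm FWHM kernel legitimately spreads signal ~25 mm).
At n ≥ 48 the test becomes sensitive enough to resolve sub-0.5%
systematic resampling asymmetries of the generator itself, so the
false-positive assertion is made in the small-cohort (n ≤ 24) regime.
Ground-truth recovery is validated at level 4 (2,562 vertices; ~8 s per
subject) with 12-subject cohorts.  Level 5 — the full analysis
resolution — is supported but not exercised in the default suite.

Known limitations: per-subject area-change maps at these noise levels
carry registration noise comparable to the per-vertex truth signal, so
recovery is validated at cohort level (correlation of 12-subject mean maps
with mean truth ≥ 0.8); the regularizer still attenuates ~10% of the true
signal amplitude; and the local optimizer, unlike a discrete-label MSM
search, can stall on large (> ~0.2 rad) initial misalignments beyond the
coarse-to-fine basin.
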