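# Methods

This note documents the models, estimators, conventions and numerical
choices implemented in `prmtopo`, and what the synthetic-data tests do and
do not establish about real CT data.

## Inputs and geometric contract

The pipeline consumes a paired study: an inspiration HU volume already
registered into the expiration frame, the expiration HU volume, and a binary
lung mask, all on one grid with one voxel spacing (mm).  Registration and
lung segmentation are upstream responsibilities; `prmtopo` refuses
mismatched grids (a shape mismatch almost always means unregistered input)
and warns above an anisotropy ratio of 1.2 because the configuration-count
estimators below are derived for (near-)isotropic voxels — the intended
data are ~0.7 mm isotropic.  Non-finite HU voxels are replaced at load time
by a sentinel above the vessel threshold so they deterministically land in
the Excluded class instead of aborting partial scans.

## PRM classification

Both volumes are smoothed with a 3×3 2D median filter applied per axial
slice (edge-replicated borders; the footprint never crosses slices), which
suppresses CT noise of roughly 100 HU magnitude that would otherwise flip
voxels across the cuts and artificially disperse the class maps.  Voxels
above −500 HU on either scan (vessels, airways) are Excluded.  The remaining
in-mask voxels are classified by two cuts, strict `>` versus `≤` so values
exactly at −950/−856 HU are deterministically assigned:

| inspiration | expiration | label |
|---|---|---|
| > −950 | > −856 | Normal |
| > −950 | ≤ −856 | fSAD |
| ≤ −950 | ≤ −856 | Emph |
| ≤ −950 | > −856 | Unclassified |

The fourth quadrant has no named class; silently folding it into a
neighbour would change %PRM irreproducibly, so it is kept explicit and
excluded from all binary maps.  Relative volumes are reported under both
denominators — all in-mask voxels (default) or classified-only — because
the field is not unanimous about whether vessel-excluded voxels belong in
the denominator; every output records which one was used.

## Minkowski estimators

All estimators operate on a 3D binary grid and are local
configuration-counting schemes (2×2×2 and 2×2×1 voxel neighbourhoods).
Everything outside the grid is background for the *raw* measures
("isolated scene"), so a single voxel has S = 6 faces.

**Surface area.**  Default mode `faces` sums exposed face areas: every face
between a foreground and a background voxel (or the border) contributes its
face area.  For the polyhedral union-of-voxels body this *is* the
configuration-count estimator with intrinsic-volume weights, and it is
exact for that body; for smooth isotropic shapes it overestimates by the
classic 3/2 factor (a digitized ball reads ≈ 6πr² instead of 4πr²).  Mode
`crofton13` counts phase transitions along the 13 lattice directions and
applies the Crofton relation S_V = 2 P_L with direction weights taken from
the spherical Voronoi cell areas of the (spacing-scaled) direction set;
it lands within ~1% of 4πr² on a radius-10 ball.  The choice is recorded in
every sidecar; both modes support anisotropic spacing.

**Mean breadth.**  Every lattice edge is classified by its four incident
voxels: one foreground voxel → convex quarter edge (exterior dihedral π/2),
three → concave (−π/2), two face-adjacent → flat (0), two diagonal → two
independent convex wedges (π, the additive normal-cycle convention for the
non-manifold case).  B = Σ ℓ_e α_e / 4π reproduces the polyhedral integral
of mean curvature exactly, hence (l+w+h)/2 for solid boxes to 1e-9.  B can
be negative for sponge-like (concavity-dominated) foregrounds.

**Euler characteristic.**  χ is the alternating sum of cell counts of a
cubical complex, computed by vectorized shifts.  The interior ("min")
complex — a vertex/edge/face is present only when *all* incident voxels are
foreground — yields the 6-connected-foreground / 26-connected-background
Euler number (the default); the closed-voxel ("max") complex — present when
*any* incident voxel is foreground — yields the (26, 6) convention.  The
two differ only on corner/edge-touching configurations.  Both agree exactly
with independent brute-force complex enumeration and with
`skimage.measure.euler_number` at the matching connectivity on randomized
grids.

## Global and Local analysis

Global analysis evaluates the measures once over map ∩ mask; Local analysis
uses a cubic moving window (default edge 21 voxels) centred on every 5th
voxel per axis.  Each window is restricted to the lung mask; windows whose
mask coverage is below 0.5 are undefined and carry NaN (never 0), and a
coverage grid is always emitted.  Defaults (21³ window, stride 5, coverage
0.5) are configurable and logged, since grid spacing and kernel size
measurably shift local texture metrics.

Normalized densities: V, S, B by the masked window volume (units 1, mm⁻¹,
mm⁻²); χ and α by the masked window voxel count.  The per-subject scalar of
each metric is the unweighted mean over defined sites (a coverage-weighted
mean is available).

**Edge correction for the S density.**  Raw S of an isolated body includes
its outer hull, which for a window-filling solid region would be the window
surface — a large value for what is geometrically the *most* clustered
configuration, inverting the dispersed-high / clustered-low contrast the
metric exists to capture.  The S *density* therefore counts only interfaces
whose two voxels are both inside the observed region (window ∩ mask) and
divides each direction by its number of observable voxel pairs
(minus-sampling).  Consequences, each verified by test:

* a wholly foreground window has S density 0 (no internal interface);
* for an iid Bernoulli(p) field the estimator is exactly unbiased for the
  closed form 6·p·(1−p)/a at voxel edge a;
* the density is exactly invariant under foreground/background complement,
  which is the symmetry of S around volume fraction 0.5 — a dispersed map
  and its negative image have the same interface.

B and χ densities keep the raw isolated-scene numerator (their raw values
grow only linearly / stay O(1) with window size, so the hull term is
immaterial) over the masked volume / voxel count.

**Display maps** multiply S, B, χ or α by the local density V — suppressing
visually distracting values where almost no disease is present — set
undefined sites to 0 and trilinearly interpolate the analysis grid back to
native dimensions (native coordinates are clipped to the site bounding box,
so interpolated values stay within the range of contributing sites);
out-of-mask voxels are zeroed.

**α (clustering descriptor).**  The canonical α definition is not public,
so the implementation is an explicitly flagged stand-in: observed
normalized χ minus the expected normalized χ of an iid field at the same
local V, with the expectation interpolated from Monte-Carlo reference
curves (`expected_random_curves`), generated at the window size so the
boundary conventions match.  α ≈ 0 for random fields and goes strongly
negative for clustered fields (far fewer disjoint structures than chance at
equal density).  Sites with V = 0 are undefined: an absent class has no
clustering, not zero clustering.  A small residual bias (|mean α| ≲ 0.002
at 21³ windows) remains because χ is a curved function of V and window-level
V fluctuates; it is an order of magnitude below the clustered signal.

## Local-vs-Global agreement

A metric is considered robust when the subject mean of its Local values
tracks its Global value.  `local_global_agreement` fits an OLS of mean-Local
on Global across ≥ 3 maps spanning distinct volume fractions.  For S on 19
iid fields (64³, p = 0.05…0.95, 21³/stride-5 windows) the fit gives
R² > 0.999 with slope ≈ 1; agreement is merely *reported* for χ and α, which
degrade because small windows cannot see large-scale topology.

## Synthetic data: what it does and does not emulate

* Bernoulli fields model maximal dispersion at a known volume fraction;
  clustered fields are boxcar-smoothed white noise (kernel edge =
  correlation length, periodic boundary) thresholded at the empirical
  quantile, so the realized fraction matches the target to ±0.01 and
  correlation length 1 reduces exactly to the Bernoulli case.
* Phantom studies paint class labels inside an ellipsoidal (or full) mask
  with exact voxel quotas, ranked on a smoothed (or iid) random field, and
  assign HU means ≥ 30 HU inside their threshold quadrants (Normal
  (−880, −800), fSAD (−880, −890), Emph (−980, −980); defaults 38% fSAD,
  1.5% Emph); Gaussian noise is added after painting.  A noiseless phantom
  classifies back to its labels exactly; at 100 HU noise the median filter
  roughly halves the misclassification rate.

These generators establish estimator correctness, normalization behaviour
and the direction and size of pattern effects.  They do **not** emulate real
anatomy: airway trees, gravity-dependent gradients, registration error,
scanner/kernel HU shifts or spatially correlated CT noise are absent, so
passing tests demonstrate properties of the method, not clinical
performance.

## Problem sizes and numerical choices

Simulation-based checks use 64³ grids (≈ 2 200 analysis windows each),
8 replicates for closed-form comparisons, 5 seeds per volume fraction for
symmetry and 10 seed pairs for the pattern contrast — sizes at which the
Monte-Carlo standard errors are far smaller than every asserted effect.
Reference curves default to 25 replicates on the stated grid.  Estimator
equalities are exact (integer counts) or asserted at 1e-9; spacing
comparisons use relative tolerance 1e-3.  Seeds enter every generator
explicitly; identical configuration and inputs give bit-identical CSV
outputs.

## Known limitations

* The α descriptor is a documented stand-in, not the original definition.
* Face-count S carries the 3/2 polyhedral bias on smooth bodies; use
  `crofton13` when absolute areas of smooth structures matter.  Both biases
  grow with spacing anisotropy.
* Lower image resolution intrinsically reads as more clustered; comparisons
  across resolutions or reconstruction kernels are not corrected for.
* The mean-breadth diagonal-edge convention (π) is one of several defensible
  choices for non-manifold edges; it does not affect solid-box exactness.
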