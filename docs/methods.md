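# Methods

`mousevbm` implements voxel-based morphometry (VBM) for the mouse brain
at ~100–250 μm voxel scale, together with the statistical validation
machinery needed to trust its inferences: residual-normality screening,
permutation-based calibration of corrected thresholds, and spatial
mapping of false positives.  This note records the models, the defaults
and why they are what they are, what the synthetic phantoms do and do not
emulate, and the numerical choices that matter.

## Coordinate conventions

Volumes carry a voxel→world matrix into bregma-origin stereotaxic
millimetres (+x left→right lateral, +y posterior→anterior, +z
inferior→superior), the reading convention of the Franklin–Paxinos mouse
atlas.  Voxel indices are 0-based.  On disk the matrix is stored in the
NIfTI-1 sform with code "aligned" and mirrored into the qform.  Whether a
given header flips left–right is a convention, not a measurable fact;
this package declares +x = right and applies it consistently.

## Affine registration with a scale/shear prior

The 12-parameter affine is composed as `T·R·S` with `S` the symmetric
positive-definite stretch.  Scales and shears parameterise `S` through
the Cholesky factor of `MᵀM`, so they are invariant to any rigid motion
composed on the left.  That invariance is what makes a population prior
over them meaningful: the shipped default holds the scale/shear
statistics of mouse brains against the atlas (scales 1.00±0.01,
1.00±0.02, 1.00±0.02 in x/y/z; shears 0.00±0.02, 0.01±0.04, 0.02±0.01
for xy/xz/yz), with diagonal covariance because only marginal spreads
are available.  The penalty is the Gaussian log-density up to a
constant, ½(v−μ)ᵀΣ⁻¹(v−μ).

Similarity is negative normalised mutual information on a 64-bin joint
histogram with partial-volume binning (each sample spreads over the two
neighbouring bins, weighted by its fractional overlap), chosen for
robustness to the contrast difference between in-vivo scans and fixed-
tissue templates.  The optimiser is Powell's method over the 12
parameters, each block scaled to its natural step (0.2 mm, 0.05 rad,
0.02, 0.02) so the derivative-free line searches take sensible first
steps, run at two resolutions (2× downsampled, then full).  Objective
values are comparable only within a resolution level, so each level
simply hands its optimum forward.  The prior enters the objective as
`prior_weight × penalty` with default weight 0.01: NMI differences near
an optimum are of order 10⁻³–10⁻², so this weight lets a 1–2 SD prior
violation compete with the image term without overwhelming it.  A run
that fails to improve on its initialisation warns and returns the best
found parameters.

Accuracy expectation: on noiseless phantoms a known transform is
recovered to better than 1% of each parameter's natural scale (relative
for scales; 0.01 absolute for shears and radians; a few hundredths of a
millimetre in translation).  Histogram-based similarity on a 0.2 mm grid
cannot localise a translation to microns, so "1%" is always understood
against each block's scale.

## Unified bias correction and segmentation

Each voxel's corrected intensity is a mixture of Gaussians, K per tissue
class (GM, WM, CSF and the implicit "everything else"), with per-voxel
mixing proportions from template tissue probability maps (floored at
10⁻⁴ and renormalised to avoid hard zeros).  The bias field is
`exp(Σ c_k φ_k)` on a separable low-frequency cosine basis; the spatial
cutoff keeps basis periods ≥ `cutoff_mm` (default 12 mm, the midpoint of
the 10–15 mm range that works for solenoid and surface mouse coils; the
test phantoms use 6 mm because their field of view is only 9.6 mm and a
12 mm cutoff would leave just the DC term).  The DC coefficient is
pinned to zero — it is indistinguishable from a global rescaling of the
class means — which also makes the bias estimate invariant to intensity
rescaling of the input.

Fitting alternates exact EM updates of the mixture (monotone by the EM
inequality, since the per-voxel mixing proportions are fixed) with a
damped Gauss–Newton step on the bias coefficients that backtracks until
the penalised negative log-likelihood decreases; the objective trace is
therefore non-increasing by construction, and the test suite asserts it.
Convergence: relative objective change < 10⁻⁵ or 30 iterations.  A class
whose posterior mass vanishes is frozen with a warning rather than
producing NaNs.  The deformation update is deliberately *not* interleaved
(normalisation is a separate stage) so each stage is independently
testable against phantom truth.

TIV is the posterior-mass integral `Σ (p_gm+p_wm+p_csf) × voxel volume`
— posteriors, not thresholded maps, so partial-volume voxels contribute
fractionally.

## Non-linear normalisation, modulation, smoothing

The warp is small-deformation: per-axis displacement (mm, world axes) on
a separable cosine basis, default 8×8×6 coefficients × 3 axes ≈ 1,150
parameters — enough to correct overall brain shape, deliberately short
of boundary-tracking registration.  The objective is the sum of squared
differences between locally mean/variance-normalised images plus
`reg_weight` × bending energy.  Both terms are physical integrals (mm³),
so their balance does not change when the same anatomy is represented at
a different grid resolution — the scale-invariance that matters when
porting human-calibrated (mm) regularisation to mouse (100 μm) data,
where bending energy scales as the fourth power of length.  The cosine
basis is orthogonal and closed under differentiation, so the bending
penalty is a diagonal quadratic form in the coefficients; optimisation
is L-BFGS with the analytic gradient (chain rule through trilinear
sampling, adjoint projection onto the basis).  Default `reg_weight`
0.05 was fixed on phantoms as the smallest weight that keeps folding
(negative Jacobians) rare; folding is logged, not forbidden.

When registering near-binary GM posterior maps, a mild 200 μm
pre-smoothing is applied first (mass-conserving, so modulation is
unaffected); matching maps of the same smoothness class avoids a
systematic inflation that appears when a crisp map is registered to a
blurred one.

The Jacobian determinant of `x + u(x)` is computed analytically from the
basis derivatives.  Modulation multiplies the pulled-back tissue map by
it, conserving total tissue quantity to <1% (interpolation error) for
every warp in the test suite.  Smoothing uses the column-normalised
kernel `G·(f / G·1)`, which conserves total intensity exactly at
boundaries; the default 400 μm FWHM follows the matched-filter argument
for the expected scale of the morphological signal.  Template building
iterates register-to-mean / subtract-mean-displacement / average, which
keeps the template at the cohort's average shape.

## GLM, FDR, random-field FWE

Voxelwise OLS over the analysis mask (cohort mean of the smoothed
modulated GM > 0.05).  Designs: two group indicator columns plus TIV,
either a single mean-centred column or TIV-by-group interaction columns
(centred within group so indicator betas stay group means).  The 6-vs-6
interaction design has 8 error df; the 42-vs-42 single-TIV design has 81
and pairs with the F-contrast [−1 1 0].

FDR is Benjamini–Hochberg step-up without the log-factor correction
(positive regression dependence assumed, as in common VBM practice).
The atrophy study uses the interaction design: with a shared TIV slope,
a chance between-group difference in brain size lets the covariate
absorb part of a genuine regional effect, which is precisely what
allowing TIV to interact with group prevents.
FWE uses the expected Euler characteristic of t or F random fields
(Worsley's closed-form EC densities, implemented here, d = 0…3) with
resel counts from residual smoothness: per-axis FWHM from the variance
of normalised-residual spatial derivatives, the actual mask volume for
the 3-D term and the mask bounding box for the lower orders (slightly
conservative for non-box masks).  The F-field densities reproduce the
t-field ones exactly through the F(1,ν) = t² identity, and Monte-Carlo
simulation of smooth t-fields shows the threshold controls familywise
error at or below nominal.  A permutation alternative takes the
(1−α) quantile of a supplied max-statistic null.  Cluster tables use
26-connectivity by default and report peaks in bregma mm.

## Validation framework

The QQ coefficient is the Pearson correlation between sorted residuals
and `√2·erfinv(2(j−3/8)/(J+¼)−1)` (standard-normal quantiles at Blom
plotting positions).  The printed source formula can be read with a
leading 2 rather than √2; the choice only rescales the quantiles and
leaves the correlation untouched, so √2 (the exact normal quantile) is
used.  A reference distribution under exact Gaussianity is generated by
simulation, optionally run until histogram bin populations stabilise
below a relative tolerance.

The permutation harness redraws balanced group labels uniformly with
replacement (the identity labelling is not excluded; at realistic n its
probability is negligible), keeps TIV fixed to subjects, recomputes the
F-map, thresholds by the chosen rule, and accumulates per-permutation
counts plus a voxelwise exceedance map.  Smoothness is re-estimated per
permutation.  The homogeneity test compares per-voxel exceedance counts
against Binomial(n_perms, α); because the chi-square comparison treats
voxels as independent, callers should decimate to a lattice at a few
times the field FWHM (`min_spacing_mm`), and the tests do.

A genuine small-sample observation from the phantoms: when inter-subject
anatomical jitter (rather than noise) dominates the variation of
near-binary GM maps, residuals at tissue boundaries are light-tailed and
the theoretical F threshold is mildly conservative (per-voxel rate
≈0.045 at nominal 0.05).  The binomial-structure checks therefore run on
noise-dominated null cohorts, where the theoretical threshold is exact;
the familywise calibration runs with full jitter and still controls at
nominal.

## The phantom generator

Stylised, analytic, and fully truth-tracked: an outer GM ellipsoid, WM
core, lateral-ventricle CSF lobes embedded in two striatum-like GM
blobs, rendered with partial volume by evaluating the geometry on a
supersampled sub-grid (default 3³ points/voxel) and averaging class
membership into per-voxel tissue fractions.  Intensities mimic
T2-weighted contrast (CSF 0.95 > GM 0.60 > WM 0.40, arbitrary units),
with per-class texture SD 0.02, a multiplicative `exp`-cosine bias field
(coefficient SD 0.1), and additive Gaussian noise (SD 0.03 — the
high-SNR limit of Rician magnitude noise).  Inter-subject anatomy is a
random small affine (0.1 mm translation SD, 0.02 rad rotation, 2% scale,
0.01 shear) plus a smooth random warp (4³ cosine coefficients, SD
0.02 mm), sized so regional volumes vary with ~6% CV — a realistic
spread for inbred mice.  The seed fully determines a cohort.

Implanted striatal atrophy is **ex vacuo**: the embedded ventricles
enlarge by an analytically calibrated factor so striatal GM drops by
exactly the requested fraction, the vacated space filling with CSF.
This choice replaced a uniform boundary erosion for a physical reason
worth recording: at 0.2 mm voxels, 15% of a ~1 mm-radius structure is a
~0.04 mm CSF film, and a sub-voxel CSF film over a GM/WM boundary is
radiologically invisible — its partial-volume intensity equals pure GM
whenever GM lies between WM and CSF, which it does in any standard
contrast.  Ventricular enlargement is both resolvable and the actual
phenotype of striatal neurodegeneration (GM loss concentrated around
enlarging ventricles).  Truth volumes integrate the subject transform's
Jacobian, so they are anatomical volumes, independent of how the jitter
stretched the rendering grid.

What the phantoms do *not* emulate: real tissue microstructure and
texture, Rician noise at low SNR, susceptibility/geometric distortion,
partial-volume physics beyond linear mixing, any real anatomy beyond
topology ("statistical, not anatomical" is the acceptance surface).
Passing tests demonstrate that the pipeline's mathematics — recovery,
conservation, calibration — behaves correctly, not that segmentation
accuracy or detection power transfer quantitatively to real scans.

## Problem sizes used by the test suite

Grids are desk-scale by design: 48³ voxels at 0.2 mm (9.6 mm field of
view), 6-vs-6 cohorts for the atrophy study and 40 exchangeable subjects
with 500 label permutations for the null calibration, with 500
Monte-Carlo repetitions for the random-field checks.  These sizes keep
every Monte-Carlo standard error well inside the asserted tolerances
while remaining comfortable on a single CPU.

## Known limitations

- The ~1,000-parameter warp cannot track individual structure
  boundaries; volumetric differences are captured jointly by partial
  warp compensation and the residual intensity difference, as in
  classic optimised-VBM.  Detection spill around a true region of a few
  voxels (one smoothing kernel) is expected.
- RFT thresholds inherit the usual assumptions (smooth, stationary,
  Gaussian-related fields); on jittery bounded tissue maps they run
  conservative rather than anticonservative in all conditions examined.
- The affine prior ships with diagonal covariance; published marginal
  SDs carry no cross-correlations.
- Segmentation refits its mixture per subject; with near-degenerate
  synthetic intensity distributions this can move a little posterior
  mass at class boundaries between subjects.  Broad, realistic class
  SDs make this negligible.
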