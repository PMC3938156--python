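# Methods

## Signal model

Tissue in every voxel is modelled as an isotropic "ball" plus up to three
perfectly anisotropic "stick" compartments with a single shared diffusivity
`d` (mm^2/s):

    S(g; b) = S0 [ (1 - sum_j f_j) e^{-b d} + sum_j f_j e^{-b d (g.v_j)^2} ]

Sharing `d` between ball and sticks is the classic ball-and-stick
assumption; it keeps the per-voxel parameter count at `2k + 2` for `k`
sticks and makes the fraction refit a simplex-constrained linear problem at
fixed `d`. Stick orientations are axial (sign-free); every reported
orientation is the antipodal representative whose first nonzero coordinate
is positive.

## Multi-fiber estimation (local ICA + ball-and-stick)

At each analysis voxel a spatial window of attenuation profiles S/S0 over
the b>0 gradients forms a data matrix (rows = window voxels, columns =
gradients). Because volume fractions vary across the window (bundle
borders, partial voluming), the single-fiber attenuation profiles act as
hidden sources mixed with nonnegative weights, and FastICA (deflation,
`exp` contrast, 500-iteration cap, fixed seed from the run configuration)
separates them. Component count is the number of PCA eigenvalue shares
>= 5%, capped at min(3, rows - 1). Each source's sign is resolved by
requiring its mixing column (physically, fractions) to have a nonnegative
sum, then shifted/scaled to a nonnegative unit-max profile. ICA
non-convergence falls back to the principal components, logged.

Each source is fitted with `a + c e^{-b d (g.v)^2}` — the free affine pair
absorbs the scale/offset indeterminacy ICA leaves on a source — by
Levenberg-Marquardt over (log d, theta, phi) with the linear pair projected
out in closed form and a Kaufman-approximation Jacobian; the orientation is
initialized from the principal axis of the log-profile quadratic form.
Flat profiles (relative modulation < 1e-3) and non-modulating fits
(b d < 0.05 at b = 1000) yield no stick.

Fractions are then re-estimated at the center voxel: for fixed orientations
the attenuation is linear in (ball, f_1..f_k), solved by nonnegative least
squares with a heavily weighted sum-to-one row followed by exact
renormalization, while `d` is optimized by bounded golden-section search on
[1e-5, 5e-3] mm^2/s. Sticks below 0.05 are pruned and the refit repeated
(at most 10 rounds); because the decomposition is deterministic given the
window, an un-pruned refit is already the alternation's fixed point, so the
loop effectively iterates over the shrinking candidate set. Degenerate
windows (< 3 usable rows) fall back to a single stick along the principal
eigenvector of a tensor fit with the voxel's FA as its fraction.

The "eleven-neighborhood" window is the center voxel, its six face
neighbors, and its four in-slice diagonal neighbors: with 1.88 x 1.88 x 3 mm
voxels the through-slice neighbors are physically farther, so the extra
members are taken in-plane. Face-only (7) and full-cube (27) layouts are
configurable.

## Robust tensor fit and scalar maps

FA/AD/RD maps come from a nonlinear least-squares tensor fit (signal-domain
residuals, log-linear initialization, analytic Jacobian) wrapped in an
iterative outlier-rejection loop: residual scale is 1.4826 x MAD with a
relative floor of 1e-8 of the signal ceiling (so numerically perfect fits
do not flag round-off), measurements with |residual| > 3 robust SD are
flagged, the fit repeats on the retained set until the flag set stabilizes
(max 10 rounds), and a final ordinary fit on the retained set is
eigendecomposed with negative eigenvalues clamped to zero. b=0 frames are
never rejected (they anchor S0); a voxel needs >= 7 retained measurements.
With an infinite threshold the procedure is exactly the plain fit. The
per-voxel rejected fraction, mask-averaged, is the subject's outlier-rate
QC scalar.

## Tractography

Deterministic propagation in continuous voxel coordinates (voxel `i` spans
`[i, i+1)`, values at centers `i + 0.5`): seeds are drawn uniformly over
the seed-mask voxel volumes (2000 by default, fixed seed), each seed
launches two half-tracks along +/- the highest-fraction eligible stick that
are concatenated. At every step the incoming direction is the trilinear
combination over the 8 surrounding voxel centers of each voxel's
smallest-turning-angle stick among those with fraction > 0.15,
sign-resolved toward the previous direction; the new direction is the
normalized equal mix of previous and incoming; the step is 0.2 voxel
widths. Termination: incoming turn > 60 degrees, no contributing voxel,
mask exit, or 2000 steps per half-track (a cap guaranteeing termination).
Streamlines with fewer than 2 points are discarded but counted. Because
trilinear blending spreads a field turn over one voxel (~5 steps), angle
terminations arise at genuinely sharp features (e.g. turns across
sub-threshold voxels), not at smooth curves — curvature below the
threshold is followed end to end.

## Pathways and single-subject flags

A streamline joins a target if any point falls in the target mask (floor to
voxel); multi-target streamlines go to the target first reached by arc
length from the seed point. Pathway voxels are those visited by strictly
more than 5 distinct streamlines; SC counts all sorted streamlines of the
pathway (before the visitation threshold), SV = pathway voxel count x voxel
volume, FA/AD/RD are unweighted pathway-voxel means. Single subjects are
flagged below `mean(ref) - 3 sd(ref)/sqrt(n_ref)` (strict) or below the
linearly interpolated 10th percentile of the reference group. Note the
three-SE criterion sits only `3/sqrt(n)` SDs below the reference mean
(~0.80 SD at n = 14), so ~21% of the reference group itself falls below it;
the self-consistency test asserts exactly that.

## Motion quality control

Each b>0 frame is rigidly registered to the first b=0 frame: 3 translations
(mm) + 3 Euler rotations (radians, x-y-z order, about the volume center),
Powell search from zero on scaled variables. The cost is the mean squared
difference of lightly smoothed (sigma 0.8 voxel), z-scored images —
equivalently normalized cross-correlation — because diffusion-weighted
frames are globally darker than the b=0 target and carry a different
tissue contrast, which a raw-intensity MSE mistakes for misalignment. The
motion index is the sum over the six parameters of the mean absolute
adjacent-frame difference; mm and radians are summed, so it is unitless,
nonnegative, and invariant to static offsets.

## Statistics

Per metric and pathway: OLS of `value ~ group + age + motion` (constant
covariates dropped with a warning); the group-effect p-value is primary,
mirroring the reported per-pathway tables, with a Wilks-lambda omnibus
across the four pathways (Rao's F, exact for a one-df hypothesis) reported
alongside. No multiplicity correction is applied to the primary p-values; a
Benjamini-Hochberg column is emitted as a clearly labelled extension.
Partial Pearson correlations correlate covariate residuals with a t
reference on n - 4 df. Age regressions are plain OLS on age. Empirical
CDFs are step functions at observed values.

## The phantom generator

`simulate_subject` renders tube bundles (polyline centerline, radius in
voxels) on the acquisition grid: constant core stick fraction with a linear
one-voxel partial-volume rim — the across-window fraction variation that
makes local source separation identifiable and that real bundle borders
exhibit. S0 carries mild structure tied to the fiber architecture (so
frames are registrable). Injections, in order: (1) a stationary
mean-reverting AR(1) rigid walk (rho = 0.7) on the b>0 frames whose step
scales are calibrated so the expected motion index equals the requested
amplitude, with rotations contributing ~2% of the index (realistic ~1
degree excursions, sub-voxel displacement); (2) whole-frame dropout with
probability `outlier_rate`, scaling a frame by U[0.2, 0.6]; (3) Rician
noise as the magnitude of a complex Gaussian pair with sigma = S0/SNR.
Everything injected is recorded in the truth object.

The cerebellum-like cohort phantom places two lateral seed ribbons and four
curved bundles to dorsal/ventral target blobs per side on a 32 x 32 x 12
grid (desk-scale: a 29-subject cohort runs end to end in minutes on one
CPU). Group defaults: 14 vs 15 subjects; group B has the core stick
fraction of one designated pathway (right-ventral by default) reduced by
30%; target motion indices are drawn from N(2.00, 0.67) for group A and
N(1.12, 0.63) for group B, and dropout rates are 9% vs 7% — the
sedated-versus-awake acquisition contrast, with the comparison group moving
more. Ages are uniform on 3.6-14.0 years. SNR defaults to 30, S0 = 1000,
d = 1.7e-3 mm^2/s (typical white matter). `simulate_metric_records`
generates record-level cohorts (no imaging) for large Monte-Carlo
calibration of the statistics.

What the phantoms do not emulate: eddy-current/susceptibility distortion,
cardiac pulsation, realistic anatomy and ROI-placement error,
multi-shell encodings, or any coupling of microstructure to age. Passing
tests therefore demonstrate correctness of the estimation, tracking and
statistical machinery under the stated noise/motion/dropout model — not
clinical-data effect sizes, which additionally depend on registration and
segmentation steps outside this package's scope.

## Numerical choices and degenerate inputs

- Diffusivity search bounds [1e-5, 5e-3] mm^2/s everywhere.
- Near-collinear stick candidates (< 5 degrees apart) are merged.
- Fractions always renormalize exactly to the simplex; reported sums obey
  `sum f_j + ball = 1` to 1e-6.
- S0 <= 0 voxels yield ball-only results; S0 <= 0 window rows are dropped
  and logged.
- Registration non-convergence returns zero parameters with a warning flag;
  a single-frame trace has index 0 with a warning.
- Empty pathway voxel sets leave scalar means undefined (None) while SC is
  still reported; empty seed masks and malformed tables raise.
- All randomness flows from explicit integer seeds; identical seeds give
  bit-identical volumes, tractograms and tables.

## Known limitations

- Angular resolution: crossings below ~50 degrees collapse to a single
  stick at SNR 30 with 55 directions; the recovery-rate curve is monotone
  in crossing angle, and this floor is inherent to the model order
  selection at this angular resolution.
- The per-source diffusivity from the offset-tolerant single-stick fit is
  biased by a few percent (offset/scale trade-off); orientations are
  unaffected and the shared `d` is refit per voxel.
- Motion is estimated but not corrected (no resampling or gradient
  reorientation); the index is a QC covariate, as in the target design.
- The single-tensor comparison field uses FA as the stick fraction — the
  standard eligibility heuristic — so threshold semantics match the
  multi-fiber field's fraction threshold only approximately.
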