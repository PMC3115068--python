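# Methods

This note records the models behind `pmdti`, the defaults that matter, and
the design decisions taken where more than one reasonable choice existed.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and units

All signals follow the mono-exponential tensor model
`S = S0 · exp(−b gᵀDg)`. Diffusivities are carried in units of
10⁻³ mm²/s throughout (so fixed-tissue white matter MD is written 0.074)
and rescaled by 10⁻³ only inside the signal equation against b in s/mm².
The model deliberately ignores bi-exponential behaviour: at
b = 4500 s/mm² and fixed-tissue diffusivities the attenuation
(b·MD ≈ 0.33) has barely departed from mono-exponential, and
multi-compartment fitting is out of scope.

Encoding directions live in the voxel coordinate frame; affine resampling
does not reorient the gradient table (the simulated distortions are
percent-level scale/shear, for which reorientation effects are second
order). World coordinates are voxel index × voxel size; phantoms are
axis-aligned by construction.

## The digital specimen

`build_specimen_phantom` generates, deterministically from a seed:

* two straight white-matter slabs crossing at the volume centre (along x
  and y; the crossing region keeps slab 1's orientation, the configuration
  that makes corticospinal-like tracts hard for single-fiber trackers);
* a cortical ribbon folded **aperiodically** in both in-plane axes, whose
  principal diffusion direction is the analytic surface normal (radial
  cortical anisotropy). A periodic fold is nearly self-similar under small
  shears and destroys registration identifiability — real cortex is
  irregular, and the phantom must be too;
* a dark band 0–2 voxels thick in the deepest cortical layer, nearly
  isotropic (FA ≈ 0.05), below both neighbouring FAs;
* a deep-gray sphere plus satellite blobs spread over the volume so every
  axis carries intensity structure;
* multi-scale multiplicative S0 texture (σ = 1.5 and 3 voxels, ~12% each).
  Registration locks onto within-tissue features; a piecewise-constant
  phantom gives a mutual-information cost pathological optima;
* an acquisition PSF: S0 and tensor elements are smoothed by σ = 0.8
  voxels and apodized so the proton-free immersion background stays
  *exactly* zero. Razor-sharp single-voxel edges do not exist in magnitude
  MRI at 0.94 mm, and they make interpolation error — not misalignment —
  the dominant artifact in any resampling pipeline. The smoothed
  transition shell carries its own label (`pv_rim`); tissue ROIs are the
  unmixed cores, and quantitative ROI comparisons additionally erode by
  two voxels, mirroring hand-drawn ROIs placed in tract interiors.

Tissue diffusivities default to the fixed-tissue per-ROI reference values
(axial/radial pairs consistent with MD = (D_ax + 2·D_rad)/3; the caudate
axial value is 0.201, correcting an obvious order-of-magnitude typo in its
commonly quoted 2.01). Tissue is parameterized by D_ax/D_rad rather than
FA; the FA of the mean tensor (e.g. 0.274 for the corpus-callosum analog)
is therefore smaller than the mean of per-specimen FAs (0.32) — a
Jensen-type gap, not an error.

Noise is Rician: the magnitude of the noiseless signal plus complex
Gaussian noise, the standard model for magnitude MRI.

## Cohorts

PMI is drawn from N(46.2, 19.9²) hours truncated to [21, 69]; SI from
N(25.2, 14.5²) months truncated to [2, 40]; the two are coupled by a
Gaussian copula with correlation 0.32 (post-truncation attenuation is
below 0.01 and is not compensated). With 11 specimens the sampling sd of
the cohort correlation is ≈ 0.28, so individual cohorts scatter widely
around the target; only the across-cohort mean pins it.

Each white-matter ROI's diffusivities decline linearly in PMI about the
reference point 46.2 h with slopes (10⁻³ mm²/s per hour) −0.0149 for
D_ax and −0.0122 for MD; the radial slope is derived as
(3·slope_MD − slope_Dax)/2 = −0.01085 so MD stays exactly linear. These
magnitudes are large relative to the reference diffusivities: over the
truncation window the linear model can leave the physical range. The
cohort ROI table is therefore an analytic linear model (the regression
stage's ground truth), while image phantoms built from cohort specimens
floor diffusivities at 10⁻⁴ with a warning. An optional FA decline for
the SLF analog (−0.019/h) is off by default because it drives FA outside
[0, 1] across the PMI window; when enabled, FA is clipped to [0, 0.99]
and (D_ax, D_rad) are re-derived from the trended (MD, FA) pair.

Gray-matter ROIs are PMI-independent.

## Distortion and correction

The distortion model has two mechanisms, matching the physics of long
fixed-tissue sessions: a B0-drift translation along the slowest
phase-encode axis, linear in repeat index (default 0.3 voxels/repeat,
config-exposed — the drift magnitude is not pinned by any published
number); and a per-direction eddy-current affine with
scale_i = 1 + α·|g_i| and shear β·g_fast·g_i in the two planes containing
the fast phase-encode axis (defaults α = 0.02, β = 0.01). Eddy maps are
deterministic in g, hence identical across repeats. Both effects compose
into a single resampling per volume.

Correction proceeds drift → average → eddy:

1. each volume of repeat k ≥ 1 is registered to its repeat-0 counterpart
   with a 1-DOF translation along the slow axis (coarse 0.5-voxel bracket
   over ±5 voxels, 0.05-voxel fine grid, parabolic vertex refinement);
2. repeats are averaged; all b = 0 volumes merge into one mean b = 0;
3. each mean diffusion-weighted volume is registered to the mean b = 0
   with a 12-DOF affine maximizing mutual information, coarse-to-fine
   (×4, ×2, ×1), Powell over parameter blocks (translation; + scale/shear;
   full 12) followed by per-parameter parabolic polish.

MI implementation choices (the cost family is standard; these details are
not): 64 bins; the registration cost uses a partial-volume-weighted joint
histogram over an *eroded fixed-image support mask* — without the fixed
mask, MI increases when the moving image's tissue/background mixtures are
pushed out of the overlap region, a well-known failure mode; both images
are pre-smoothed by ~1 voxel, which suppresses the integer-shift local
maxima that histogram costs exhibit under linear resampling. The affine
search is parameterized about the image centroid (not the volume centre),
which decouples translation from scale/shear when tissue sits off-centre;
the result is converted back to volume-centred parameters. The public
`mutual_information` function uses plain hard binning so that
MI(A, A) = H(A) holds exactly.

Two honest limitations, quantified by the test suite rather than hidden:
registering a diffusion-weighted volume to a b = 0 under MI carries a
contrast-induced parameter bias of order 0.5–1.5% in scale for some
directions (the attenuation pattern changes with g; this is a property of
MI DW→b0 registration generally, and one reason modern in-vivo pipelines
moved to signal-model-based eddy estimation); and parameter recovery is
therefore assessed as a pooled correlation over all transform parameters
across volumes, plus the corrected-vs-uncorrected FA-error contrast.

The corrected output is produced by resampling each **raw** volume exactly
once through the composed drift+eddy inverse with cubic-spline
interpolation; the registration itself runs on cheap linear intermediates.
Cascaded resampling blurs the data enough to negate most of the
registration benefit on percent-level distortions.

## Tensor fit

Two-pass weighted log-linear least squares: OLS on log-signal, then a
normal-equation solve with weights equal to the squared predicted signals.
Non-positive intensities are clamped to 10⁻⁶ of the series maximum and
flagged; flagged voxels are excluded from ROI statistics. Negative
eigenvalues are clamped to zero for the scalar maps and flagged rather
than refit under a positivity constraint — the standard total-map
compromise. Zero tensors yield FA = 0, flagged, never NaN.

## Cohort regression

For each index (FA, MD, D_ax, D_rad) and each column (five white-matter
ROIs plus the "Average" column, the per-specimen mean over those five
ROIs): a single regression on PMI, one on SI (for plots), and a multiple
regression on PMI + SI (for inference; it linearly adjusts for the
PMI–SI correlation). Correction is Bonferroni within each predictor's
family of 4 × 6 tests (method and family config-exposed); reported tables
blank coefficients whose corrected p exceeds 0.25.

## Partial-volume simulation

"Effective resolution" is interpreted as quadrature FWHM addition: the
blurring kernel has FWHM = sqrt(target² − native²), e.g. σ = 0.791 mm to
take 0.73 mm data to 2 mm. Convolution is zero-padded (the immersion
background is zero-signal by construction; metrics on the no-background
gray–white fixture exclude a 6-voxel FOV margin). Three pipelines are
compared on the native grid: blur-the-raw-data-then-refit (the reference),
blur the FA map, and blur the tensor elements then recompute FA.

The dedicated gray–white fixture is a white-matter slab in cortex-like
tissue of the *same MD* with perpendicular anisotropy, which isolates the
anisotropy-mixing mechanism that thins tracts at coarse resolution.
Apparent thickness is the mean suprathreshold extent of FA profiles across
the slab. Note a quirk of the fixed-tissue regime: half the slab's
interior FA (0.137) sits marginally *below* the ambient cortical FA
(0.132) — the weak FA contrast of fixed tissue — so thickness measurements
here threshold at the midpoint of the two compartment FAs; the threshold
is an explicit argument.

## Tractography

Deterministic tensor-line streamlining: bidirectional Euler integration of
the principal diffusion direction with sign continuity and trilinear
interpolation (corner PDDs sign-aligned to the previous step before
averaging). Termination: FA below threshold (default 0.10), bending above
45° per step, leaving the volume, or a length cap. Step defaults to half
the smallest voxel. An optional per-step angular jitter emulates the
spread of probabilistic tracking but is off by default. The global
strategy seeds every voxel of a seed region and retains exactly those
streamlines intersecting both inclusion masks (nearest-voxel membership);
no exclusion masks. The multi-fiber Bayesian machinery that a
probabilistic tracker would use is intentionally not reimplemented — the
gating strategy is the subject here, and the crossing-slab phantom shows
the expected single-fiber behaviour (streamlines do not jump to the
crossing slab).

## Protocol arithmetic

Per-volume time is ceil(PE lines / lines per segment) × slice-encodes ×
TR. Timing deliberately ignores the partial-Fourier factor: the printed
per-volume times of both fixed-brain protocols (6:22 at 0.94 mm with
192 PE lines / 32 per segment / 120 slices / TR 530 ms; 17 min at
0.73 mm) are consistent only with full phase-encode coverage, and the
matrix dimension that reproduces them (192, resp. 254) is taken as the
phase-encode axis. A `partial_fourier_timing` flag provides the
alternative. Session time is (directions + b0s) × repeats × volume time.

The SNR-efficiency model — fully-spoiled steady state,
sin α (1−E1)/(1−E1 cos α)/√TR — is exploratory: it is one plausible
reading of the T1-recovery-versus-averaging trade-off. At T1 = 340 ms
(fixed white matter) and flip 75° its optimum falls below the 500–700 ms
working range usually quoted for such protocols, and the function warns
accordingly; no acceptance check depends on it.

## Problem sizes and determinism

The evaluation battery (`pmdti.evaluation`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) runs registration
experiments on 32³ phantoms with 6 encoding directions and 2–3 repeats,
the noise-bias experiment on a 48³ phantom with the full 54-direction
protocol, the correction contrast on 48³, cohort statistics on 11-specimen
cohorts (150 noisy replicates for slope bias, 500 null cohorts for the
type-I rate), and the partial-volume experiment on the 48³ gray–white
fixture. Every stage derives its RNG seed from a master seed and a stage
name hash, so runs are exactly repeatable and stages are independently
reproducible.

## Known limitations

* The synthetic specimens emulate geometry, contrast, texture and noise of
  fixed whole-brain data, not anatomy: passing tests demonstrate correct
  mechanics and calibrated statistics, not performance on real brains
  (where susceptibility effects, coil shading, and fixation
  inhomogeneity — all unmodelled — matter).
* MI-based DW→b0 eddy registration carries the contrast bias noted above.
* Gradient reorientation under affine correction is omitted (percent-level
  distortions only).
* The cohort PMI effect is a linear analytic model with printed-magnitude
  slopes; it is internally consistent for slope-recovery statistics but
  not physically plausible at the extremes of the PMI window.
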