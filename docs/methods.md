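# Methods

This note documents the models, algorithms and numerical choices behind
`exsrrf`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Expansion microscopy physically magnifies a specimen ~3.7–3.8× before
imaging; combining it with super-resolution radial fluctuations (SRRF)
processing of widefield time stacks yields an effective resolution fine
enough to segment and measure nanoscale tissue structures — e.g. the
~40 nm slit diaphragm (SD) bridging kidney podocyte foot processes
(FPs), or the endoplasmic-reticulum network under stress.  The package
implements the computational stages of that workflow: drift
registration of time stacks, the SRRF transform, registration-quality
metrics, and the ridge-based "nanometrics" quantifications (density,
local spacing, width profiles, two-point resolution, expansion factor).
Everything runs on seeded synthetic data with known ground truth.

## Registration

Each frame is aligned to frame 0 of a reference channel.
Preprocessing follows the order smooth → percentile-zero → histogram
match: a Gaussian of sigma 1 px suppresses pixel noise, zeroing
everything at or below the 90th percentile keeps only the brightest
structures, and histogram matching makes the moving frame's intensity
distribution comparable to the reference before correlation.  The
shift is the argmax of the cross-correlation, refined by
discrete-Fourier-transform upsampling to 1/100 px
(`skimage.registration.phase_cross_correlation` with plain rather than
phase normalization — on percentile-sparsified frames the plain
correlation proved markedly more stable).  The estimated drift is
removed from **all** channels by one first-order interpolation
(integer part acts as crop-and-pad, fill value configurable; a flag
rounds to whole pixels instead).  Per-frame overlap masks record the
region still backed by measured data.

Degenerate frames that are empty after preprocessing fall back to
raw-intensity correlation with a logged warning rather than aborting
the stack.

Correlation-based estimation assumes a dominant rigid translation; it
is biased on smooth, quasi-periodic or nearly featureless scenes
(rotations and non-rigid motion are out of scope).  The shift-recovery
benchmark therefore uses structure-rich filament phantoms, on which
the cohort RMSE is well below 0.2 px for drifts up to 10 px at peak
SNR 5.

## SRRF radiality

For every position `c` of an `M`-fold magnified grid (subpixel centres
at `(i + 0.5)/M − 0.5` in source coordinates), the intensity gradient
(centred differences; optionally Gaussian-smoothed first — the tissue
preset) is sampled at `K = 2A` ring points `p_k = c + r(cos θ_k,
sin θ_k)`.  Each sample contributes `sign_k · max(0, 1 − d_k/r)`,
where `d_k` is the perpendicular distance from `c` to the line through
`p_k` along the interpolated gradient `g_k`, and the sign is positive
when `g_k` points toward `c`.  The radiality is the ring average,
clipped at zero (positivity constraint) and multiplied by the
interpolated frame intensity (intensity weighting).  Zero-gradient
samples contribute nothing.  Gradients are interpolated bilinearly and
the weighting intensity with an interpolating cubic B-spline, both with
reflect boundaries; when the positivity constraint is active the
weighting intensity is clipped at zero too, so read noise cannot flip
the sign of the output.

The triangular convergence weight is deliberately the simplest form
consistent with the radial-symmetry idea; the kernel lives in one
isolated function (with a compiled and a vectorized implementation
kept equal to 1e-12 in tests) so alternatives can be swapped.
Steeper powers of the same weight were evaluated and narrowed the
radiality peak slightly but degraded peak localization under noise;
the linear form is the default.

Aggregation over frames is the temporal radiality average (TRA).
Higher-order temporal statistics (TRAC2/4) are out of scope.

**Anti-patterning.**  The magnified grid partitions into `M × M`
subpixel-offset classes; systematic class-mean imbalance shows as a
`1/M` lattice artefact.  Each class is rescaled toward the common
class-mean average, weighted by `max(0, 1 − SE²/Δ²)` — the fraction of
the observed imbalance `Δ` that exceeds the standard error of the
class mean.  A constructed artefact (imbalance far above sampling
noise) is equalized fully; on sparse or noise-dominated maps the
correction vanishes instead of amplifying noise, which blind
multiplicative equalization was observed to do (it shifted the peak of
single-emitter maps by up to a magnified pixel).  A final global
rescale preserves the image mean exactly.

**Resolution behaviour and its limits.**  On two-emitter nanoruler
stacks the SRRF output separates pairs at and above ~1.2× the
widefield FWHM while the 50-frame widefield average separates none of
the tested distances (its inter-peak valley never falls below the
signal-free cut).  Below ~1× FWHM, first-order temporal averaging
cannot separate the pair regardless of blinking duty cycle: whenever
both marks emit in the same frame the blended spot is unimodal, so its
gradients converge on the midpoint and the radiality map itself peaks
there; in addition the single-mark radiality halo at the midpoint
already reaches ~2 × 9% of the peak at 0.8 FWHM.  The valley therefore
stays above any sensible "no signal" threshold.  Sub-PSF pair
separation requires sparse activation with many more frames, or the
higher-order temporal analyses that are explicitly out of scope; the
benchmark asserts the achievable part (monotonicity in distance,
strict advantage over widefield at ≥1.2 FWHM) and this limitation is
stated rather than papered over.

## Drift-quality metrics

Per-frame drift magnitude is the 2-norm of the estimated shift,
summarized as the mean over moving frames and the final-frame value.
MSSIM and MSE are computed against frame 0 on the bounding box of the
overlap mask — padded borders never enter the metrics — on raw
intensities, so before/after values share a scale (the SSIM window is
7×7, Gaussian-weighted, sigma 1.5; its stabilizing constants use the
joint intensity range of the frame pair).  Deltas are before − after:
negative MSSIM delta and positive MSE delta mean registration helped.
Cohorts are split at `mean + 0.5 s.d.` of the per-stack mean offsets
("0.5 s.d. from the mean"); an absolute `0.5 s.d.` cut is available
via a flag, and the mean offset is the stratification statistic (less
noise-sensitive than the last-frame offset; both are reported).

`ridge_ssim` scores segmentation-readiness: the structural similarity
between an image (rescaled to [0, 1]) and its ridge response; constant
inputs compare as identical through the stabilizing constants.

## Nanometrics

**ROI extraction** downsamples to 25% (local mean), optionally zeroes
pixels below 5% of the maximum (SD preset; the original macro's
"low-level noise" cut is unspecified — 5% is this package's
documented choice), smooths (sigma 8 for SD; sigma 8 then 10 for ER),
Otsu-thresholds (constant images degenerate to all-on/all-off), fills
holes (plus a disk-5 closing for SD), and keeps components above
5 000 downsampled pixels before nearest-neighbour upsampling.  The
5 000-px cut presumes full-frame micrographs (roughly 512×512 after
downsampling, where it is ~2% of the frame); it scales with image
area, and the phantom benchmarks — whose downsampled frames are only
96×96 — use a proportionate 700-px cut.

**Ridge segmentation** takes the Meijering neuriteness response
maximized over scales, min-max rescales it to [0, 1] (the published
0.2 / 0.25 thresholds are only meaningful on a normalized response),
thresholds, removes objects under 125 px (ER preset) and opens with a
disk of radius 1.  The default scale set is (1.0, 1.5): on
calibration lattices of known width/period, these scales reproduce the
geometric density within ~8%, whereas adding sigma 2–3 inflates
3–4 px line masks by 25–65% — scale sets are configurable and should
be matched to the expected ridge width (~2× the widest sigma).
A caveat found during calibration: integer-period lattices aligned to
the pixel grid lock every line to one subpixel phase, quantizing
thresholded mask widths to odd or even pixel counts; calibration is
therefore done at oblique orientations, where the phase dithers along
each line.

**Density** is ridge pixels within the ROI over ROI pixels (NaN when
the ROI is empty).

**Local spacing** is the local-thickness transform: the spacing at a
pixel is the diameter of the greatest disk inside ROI-minus-ridges
that contains it.  Discretely, a disk centred at `c` covers `p` when
`|p − c| < r(c)`, with `r(c)` the exact Euclidean distance to the
nearest excluded pixel (image border counts as excluded).  The
implementation paints disks in descending radius order using exact
integer squared radii and FFT dilation; tests require bit-exact
agreement with an exhaustive brute-force oracle.  Summary statistics
are the mean, median (the per-image statistic used downstream), s.d.,
and an *area fraction* implemented as |ROI∖ridges| / |ROI| — the share
of the ROI occupied by inter-ridge space; the original macro's
definition is not stated precisely, so this interpretation is
documented here.  The 8-bit display map sends the minimum spacing to 0
and the maximum to 255.

**Width profiling** thresholds the image with the iterative-intermeans
(isodata) algorithm — ImageJ's "default" — implemented as the smallest
histogram cut at or above the average of the two class means; a
brute-force fixed-point scan is the test oracle.  The width is the
length of the above-threshold run crossed by the profile (the run
containing the profile maximum), in profile units: a band crossed at
45° reads √2 longer.  Physical widths multiply by the pixel size and
divide by the expansion factor.  Peak-to-peak distances use the two
dominant profile maxima with parabolic subpixel refinement.

**Foot-process segmentation** thresholds (isodata), inverts so the
spaces between bright separators become foreground, and splits them by
watershed on the inverted distance transform with markers at distance
maxima.  Per-label widths are read from a profile perpendicular to the
label's principal axis through its distance-transform maximum; labels
touching the image border are excluded.  The published workflow's
final supervised curation step is out of scope.

**PSF separation** normalizes the crop, treats everything below 10% of
the maximum as signal-free (an automated stand-in for the supervised
histogram adjustment of the original protocol), finds dominant local
maxima (≥50% of the global maximum, ≥3 px apart), and declares the
pair separated when the straight path between the two brightest
crosses at least one signal-free pixel.

**Expansion factor** is the ratio of post- to pre-expansion
peak-to-peak distance.  The benchmark references a micrometre-scale
(3 µm) correlative distance, as in practice, perturbs each peak with
1 px Gaussian localization noise and averages the per-pair ratios over
20 seeds; at that scale the ratio estimator's denominator-noise bias
is below 0.1%.

## Synthetic data

Frames are sums of isotropic Gaussian PSFs (sigma 1.3 px ≈ 200 nm FWHM
at the default 65 nm pixels) over emitters that blink as independent
per-frame Bernoulli trials (default on-probability 0.6), translated by
a drift model (linear, seeded random walk, or explicit trace), with
Poisson shot noise and Gaussian read noise.  The default brightness
(100 counts) and read noise (sqrt(300) counts) give a peak SNR of 5 —
a deliberately unforgiving acquisition.  Nanoruler marks default to
brightness 400 (peak SNR ≈ 16): a mark carries tens of fluorophores
and nanoruler acquisitions are exposure-optimized calibration
measurements, and at SNR 5 the rectified-noise floor of the radiality
average (positivity clipping before temporal averaging turns zero-mean
noise into a positive background) sits just at the separation
criterion's signal-free cut, making the resolution benchmark measure
the noise floor instead of resolution.

Registration benchmarks use emitters laid ~1.2 px apart along wavy
filaments so the frames are structure-rich like tissue; isolated-spot
scenes leave most SSIM windows noise-dominated, where registration
cannot (and should not) show an improvement.

Ridge lattices are anti-aliased stripe patterns with known density
`width/period`; the default half-pixel phase keeps axis-aligned
midlines off exact pixel centres.  The interdigitation phantom draws a
square-wave meander (the SD) whose thickness is the SD gap and whose
lobes are the FPs; "effacement" deletes a seeded fraction of meander
segments (merging neighbouring processes) and is typically paired with
a widened FP width.  Deletion fraction 1 leaves an empty separator
channel.

What the generators do *not* emulate: realistic photophysics (triplet
states, bleaching), correlated or structured background, optical
aberrations and anisotropic PSFs, gel distortion, and the
heterogeneity of real tissue.  Passing benchmarks therefore shows the
algorithms are correctly implemented and behave sensibly under
controlled conditions, not that the full workflow is validated on
microscope data.

## Numerical choices and degenerate inputs

- Coordinates are 0-based `(row, col)` with pixel centres at integers.
- All-zero frames raise a shift-estimation error naming the frame;
  constant frames preprocess to zero and trigger the raw-intensity
  fallback.
- Otsu on constant input maps to all-on (positive) or all-off (zero).
- Empty ROIs yield NaN density and missing spacing statistics with a
  logged warning; empty ridge sets are valid (density 0).
- Ring samples with zero gradient contribute zero radiality; the
  zero-gradient guard is an absolute 1e-12 on the gradient norm.
- Problem sizes in the test-suite benchmarks (64×64 registration
  stacks, 32×32 SRRF stacks, 256×256 lattices, 384×384 phantoms,
  48×48 oracle masks) were chosen so every stage runs at full fidelity
  while the whole suite stays lightweight on a single CPU.
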