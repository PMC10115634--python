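# exsrrf

Computational pipeline for **expansion microscopy + super-resolution
radial fluctuations (ExSRRF)**: drift registration of widefield time
stacks, the SRRF radiality transform, registration-quality metrics, and
ridge-based nanoscale morphometrics ("nanometrics") — written for
microscopists and image analysts who quantify nanoscale tissue
structures (e.g. the ~40 nm kidney slit diaphragm, or ER networks)
from time-stacked fluorescence acquisitions of expanded specimens.

## What it computes

**Registration.** Every frame of a `T×C×Y×X` stack is aligned to frame
0 of a reference channel: Gaussian smoothing (σ = 1 px), zeroing of the
lower 90th intensity percentile, histogram matching, then subpixel
shift estimation by DFT-upsampled cross-correlation (1/100 px). The
shift is removed from all channels, cropped and padded to size.

**SRRF.** On an `M`-fold magnified grid, the radiality at `c` averages
`sign_k · max(0, 1 − d_k/r)` over `K = 2A` ring samples, where `d_k`
is the distance from `c` to the line through ring point `p_k` along
the local intensity gradient, and the sign is positive for gradients
converging on `c`. Maps are intensity-weighted, clipped at zero,
averaged over frames (temporal radiality average) and corrected for
the `M`-periodic lattice artefact. Presets match the published
parameter sets (`nanoruler`: r = 0.5, M = 10, A = 8; `tissue`:
gradient smoothing on).

**Drift quality.** Per-frame offset norms (mean and last-frame
summaries), MSSIM/MSE versus frame 0 on the overlap region before and
after registration (`before − after`; negative ΔMSSIM and positive
ΔMSE mean the registration helped), low/high-drift stratification at
`mean + 0.5 s.d.`, and a ridge-SSIM score of segmentation readiness.

**Nanometrics.** ROI extraction (downsample → smooth → Otsu →
morphology → size filter), Meijering ridge segmentation with the
published 0.2/0.25 thresholds on a normalized response, ridge density
within the ROI, local spacing as the largest-inscribed-disk
(local-thickness) transform with mean/median/s.d./area-fraction
summaries and an 8-bit display map (0 = shortest, 255 = largest),
profile-based width measurement with isodata ("default") thresholding,
watershed foot-process segmentation, nanoruler PSF-separation calls,
and expansion-factor estimation (post/pre peak distance, ≈3.7–3.8×
for this protocol).

**Synthetic data.** Seeded generators for every input class: blinking
Gaussian emitters with drift and shot/read noise, filamentous
registration phantoms, nanoruler pairs at fabricated distances, ridge
lattices of known density, and interdigitating foot-process/slit-
diaphragm phantoms with an "effacement" mode.

## Worked example

```python
import numpy as np
from exsrrf import (SyntheticSpec, filament_emitters, make_emitter_stack,
                    register_stack, similarity_metrics, offset_summary,
                    SrrfSettings, srrf_process, make_nanoruler, psf_separation)

# 1. simulate a drifting widefield acquisition of filamentous structures
spec = SyntheticSpec(image_shape=(64, 64), emitters=filament_emitters(seed=42),
                     frames=50, drift_mode="linear", drift_rate=(0.12, -0.06),
                     seed=42)
stack, truth = make_emitter_stack(spec)

# 2. register frame-to-first and score the correction
registered, trace = register_stack(stack)
mean_off, last_off = offset_summary(trace)
metrics = similarity_metrics(stack, registered, trace)
print(f"mean offset {mean_off:.2f} px, last offset {last_off:.2f} px")
print(f"delta MSSIM {metrics.delta_mssim:+.3f}, delta MSE {metrics.delta_mse:+.1f}")

# 3. SRRF-process a nanoruler pair at 1.2x the PSF FWHM
stack_nr, truth_nr = make_nanoruler(distance_nm=239.0, expansion_factor=1.0,
                                    image_shape=(32, 32), seed=3)
srrf_img = srrf_process(stack_nr, settings=SrrfSettings.nanoruler())
sep, maxima = psf_separation(srrf_img.data)
wf_sep, _ = psf_separation(stack_nr.data[:, 0].mean(axis=0))
print(f"true separation {truth_nr['separation_px']:.2f} px")
print(f"SRRF separated: {sep}; widefield separated: {wf_sep}")
```

Output:

```
mean offset 3.38 px, last offset 6.62 px
delta MSSIM -0.374, delta MSE +5581.2
true separation 3.68 px
SRRF separated: True; widefield separated: False
```

The simulated stage drift accumulates to 6.6 px by the last frame;
registration recovers and removes it, raising the structural
similarity to frame 0 (ΔMSSIM < 0) and lowering the squared error
(ΔMSE > 0). The nanoruler pair 3.68 px apart is unresolved in the
plain 50-frame average but shows two maxima separated by signal-free
pixels after SRRF.

A command-line interface mirrors the library:

```bash
exsrrf simulate emitter-stack --spec spec.yaml --seed 7 --out stack.ome.tif --truth truth.json
exsrrf register --in stack.ome.tif --out registered.ome.tif --trace trace.csv
exsrrf quality --before stack.ome.tif --after registered.ome.tif --trace trace.csv --out metrics.json
exsrrf srrf --in registered.ome.tif --preset nanoruler --out srrf.tif
exsrrf nanometrics --in srrf.tif --preset sd --pixel-size-nm 6.5 --out report.json
```

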