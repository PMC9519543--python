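# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `spiris`. It is the package's own account of its science;
every number quoted here is computed by the test suite or the worked
examples, not asserted from elsewhere.

## The measurement being modelled

A single-particle interferometric reflectance sensor images a DNA microarray
on a layered Si/SiO2 substrate. Each captured target molecule carries a gold
nanorod label and shows up as a diffraction-limited bright spot whose
contrast depends on defocus. Two assay formats are supported:

* **Endpoint**: the chip is incubated, washed and imaged once as a defocus
  z-stack; the response is the particle count per spot.
* **Kinetic**: the target/label mixture flows over the chip while a
  time-lapse movie records every binding and debinding event; the response
  is the binding rate (events/hour) per spot, and counting is *total
  binding* — a complex that binds and later debinds still counts once.

## Event model (simulator)

Binding events on one spot form a homogeneous Poisson process with rate

    lambda(c) = k (c / c_ref)^(2/3) + lambda_ns

The 2/3 exponent is the diffusion-limited sheet-density scaling of the
surface binding rate at low volumetric concentration; `lambda_ns` is a
concentration-independent nonspecific rate that is the only signal on blank
(zero-target or non-complementary control) spots. Event positions are
uniform on the spot disc. Dwell times are exponential with mean `tau`,
except a fraction `p_perm` of binders that never debind within the
experiment; the field's software eliminates tracking false decisions using
only a dwell-time *prior*, with no published distribution, so the
exponential-plus-permanent mixture is this package's modelling choice with
both knobs config-exposed.

Rendering: each bound particle adds an isotropic Gaussian bump (sigma =
`psf_sigma`, peak amplitude `particle_contrast * background_level`) to the
background; the nanorod's orientation/polarization-dependent visibility is
deliberately abstracted into that one scalar amplitude. Per-pixel Gaussian
noise of SD `shot_noise_scale * background_level` models shot noise. In
z-stacks, amplitude follows the antisymmetric defocus curve
`a(z) = contrast * sin(2 pi z / period) * exp(-z^2 / (2 width^2))`, which
reproduces the two observable facts the detector relies on: the contrast
flips sign across focus and the per-pixel max-min over the stack is large at
particle sites.

### Default study conditions

| parameter | default | why |
|---|---|---|
| `c_ref` | 1 fM | rate constants stay human-scale |
| `rate_constant` k | 170 events/h/spot at 1 fM | places the planted kinetic LOD near 10 aM (below) |
| `scaling_exponent` | 2/3 | diffusion-limited sheet-density law |
| `nonspecific_rate` | 2 events/h/spot | realistic low blank activity; see planted LOD |
| `mean_dwell_time` | 300 s | stable hybridization, minutes-scale dwell |
| `permanent_fraction` | 0.25 | a sizable fraction of binders persists |
| `duration` | 1800 s | responses recorded within ~30 min suffice for rates |
| `frame_interval` | 10 s | ~6 frames per typical transient dwell |
| `psf_sigma` | 1.5 px | diffraction-limited spot at moderate sampling |
| `particle_contrast` / `shot_noise_scale` | 0.15 / 0.01 | contrast-to-noise 15 |
| `concentrations` | 100 aM … 1 pM, decades | the standard-curve range |
| grid pitch / replicates | 200 um / 16 | the spotter layout |
| flow rate | 5 uL/min | metadata only; transport is not simulated |

**Planted LOD.** The kinetic LOD is defined as the concentration where the
rate law crosses `blank mean + 3 SD`. For blanks the dominant scatter is
Poisson counting noise, SD = `sqrt(lambda_ns / T)` per replicate. With the
defaults (`lambda_ns = 2/h`, T = 0.5 h) the threshold is 2 + 3*2 = 8
events/h and the planted LOD is `1 fM * (8/170)^(3/2)` = 10.2 aM.
`planted_lod`/`nonspecific_rate_for_lod` expose this algebra.

## Detection

Order of operations for a kinetic movie: optional temporal averaging
(non-overlapping blocks of n frames; the incomplete tail block is dropped,
not padded), per-pixel temporal baseline normalization, pseudomedian
background subtraction, ZNCC scoring, global threshold, keypoint filtering.
For an endpoint z-stack: per-pixel z-median normalization, max-min
differential image, then the same background/ZNCC/threshold/filter chain.

**Temporal baseline.** Dividing by each pixel's temporal *median* is the
classical choice, but it fails for any binder that occupies its pixel for
more than half the movie (an early permanent binder simply becomes part of
the baseline and its binding step disappears; with `p_perm = 0.25` that
would silently drop ~12% of events). `temporal_baseline` therefore also
offers a lower quantile and, as the `detect_stack` default, a robust
minimum: the minimum over 5-frame block means. The block mean tames noise;
the minimum tolerates arbitrarily long occupancy provided each pixel is
particle-free at some point. Its small downward noise bias is irrelevant
because ZNCC is invariant to local offset and scale. All three methods are
config-exposed and tested.

**Pseudomedian background.** The background estimate is a separable
pseudomedian: within each kernel-sized window, the median along rows, then a
maximum filter and a minimum filter along columns, averaged. It is evaluated
on a sparse grid (stride = kernel//2) and bilinearly interpolated; on smooth
fields the sparse and dense evaluations agree to < 2% of the dynamic range
(tested), and at these image sizes the dense pass is cheap, so sparseness is
an output contract rather than an optimization. A compact bright structure
smaller than the kernel is fully rejected from the background (a 3x3 bump of
+100 on a flat field leaves the estimate within 10 grey levels at its
centre; tested). The default kernel (11 px at `psf_sigma` = 1.5) is the
smallest odd size covering the PSF *support* (~6 sigma) plus a margin: with
a kernel merely at the 3-sigma scale, the row medians absorb a large part of
a PSF-sized particle into the background and distort the blob shape, so the
support scale is the right reading of "slightly larger than the PSF" for a
background estimator.

**ZNCC.** Scores are zero-normalized cross-correlations in [-1, 1] between
the background-subtracted image and a zero-mean, unit-norm kernel (measured,
or synthesized as a Gaussian from `psf_sigma`). Boundaries use reflective
padding; windows with negligible variance score exactly 0, which makes
noiseless blank regions silent instead of 0/0. For pure iid noise the score
SD is ~`1/sqrt(kernel pixels)` (~0.09 for 11x11), so the maximum over a
64x64 field stays below the 0.6 threshold with large margin — false
positives come essentially only from noise exceedances that the tracking
stage's duration filter then removes.

**Keypoint filter.** Blobs are 8-connected components of the thresholded
score map. Area is the pixel count; perimeter is the count of border pixels
(component pixels with a 4-neighbour outside); centroids are score-weighted,
giving sub-pixel localization (<= 0.5 px noiseless, <= 1 px at default
noise; tested). A blob survives iff area lies in `area_range` (default
4–200 px^2) and area/perimeter in `ratio_range` (default 1.05–4.0): a
radius-3 disc scores ~1.8 and passes, a 1-px-wide line scores exactly 1.0
and is rejected. The threshold (0.6), area and ratio bounds are not
published for the original instrument; they were calibrated once on
simulated scenes at the default contrast/noise and frozen.

## Tracking

Greedy per-frame nearest-neighbour association within
`association_radius` (2 px): pairs are matched in order of increasing
distance (ties: lowest track id), unmatched detections open tracks,
unmatched tracks end. Global (Hungarian) assignment is unnecessary because
bound particles do not move; the greedy matcher is exact for well-separated
sites and is verified against a brute-force interval reconstruction on all
instances with <= 20 detections. Gap repair merges co-located tracks whose
temporal gap is <= `max_gap` (2 frames, from the dwell-time prior), applied
to convergence (idempotent); re-binding after a longer gap is deliberately a
*new* binding event, matching the cumulative-total definition. Tracks
supported by fewer than `min_duration` (2) frames are removed as
single-frame positives.

Known limitation: in dense scenes two particles closer than roughly the blob
diameter merge into one detection, and a new binder landing within the
association radius of a live track is swallowed by it. Both losses grow with
occupancy; at the default conditions (~40 events on a 45-px-radius spot)
aggregate event recovery is within ~10% of truth (tested), and because the
same efficiency factor applies to calibration points and blanks alike, it
largely cancels in the LOD.

## Quantification

**Rates.** The binding rate is the OLS slope of the cumulative curve versus
time in hours (default window: the whole incubation after an optional
burn-in). The reported standard error is the Poisson counting error
`sqrt(rate / window_h)`, not the iid OLS residual error: cumulative curves
have strongly autocorrelated residuals and the naive OLS SE undercovers
several-fold (~10% coverage at 3 SE, measured), while the counting error
gives the intended >= 95% coverage (tested).

**Kinetic LOD.** On double-log axes, a free line and a fixed-slope (2/3)
line are fitted; the LOD is where the fixed-slope line crosses
`blank mean + 3 SD`. "Steepest possible slope" has no published formula; it
is operationalized as the upper bound of the free slope's 95% CI, refitted
for its own least-squares intercept — its crossing gives the interval's
upper end, the free best-fit crossing the lower end, and the interval is
widened if needed so it always brackets the conservative estimate. A
crossing outside the measured response range sets `extrapolated=True`. Zero
responses are excluded from log fits with a warning, never patched with
pseudo-counts; an all-zero blank requires an explicit `threshold_floor`.

**Endpoint LOD.** `3.3 sigma / slope` presumes a linear response, so the
slope is taken on the linear scale as the local derivative of the power-law
fit at the lowest measured concentration (`a b c_min^(b-1)`); a global
linear fit is available by flag. Blanks default to non-complementary control
spots; zero-concentration chips are an equally valid blank source.

**Copies.** `copies = c * V * N_A` with N_A = 6.02214076e23; 10 aM in
0.2 mL gives 1204.4 copies.

## Numerical and design choices

* Coordinates are 0-based, pixel-centre, x = column, y = row, stated in
  output headers.
* All fits in log10; SI molarity strings ("100aM", "1fM") parse
  case-sensitively.
* Determinism: a configuration seed drives a single `numpy` Generator;
  identical config + seed reproduce bit-identical events, frames and CSVs.
* Keypoint centroids clip negative scores to zero before weighting
  (degenerate all-zero components fall back to unweighted centroids).
* `temporal_average` errors if n exceeds the frame count; `normalize_stack`
  errors on non-positive per-pixel medians (corrupt input) and requires >= 3
  frames; stack readers fail closed on truncated files and mixed/RGB pages.

## Problem sizes used in validation

The acceptance battery runs at reduced problem sizes chosen as the package's
own validation design: detection fidelity on 128x128 single frames with 50
planted particles; tracking equivalence on 200 random instances of <= 20
detections; the scaling-law recovery on event streams (5 decades x 50
replicates); and the end-to-end LOD recovery on 64x64, 90-frame movies
(3 concentrations x 3 replicate spots + 12 blanks, 100 seeds), where the
median recovered LOD must lie within a factor 2 of the planted 10.2 aM.

## What passing tests do and do not show

The simulator reproduces the statistical structure the pipeline relies on —
Poisson arrivals with the 2/3 rate law, exponential dwells, defocus-shaped
contrast, shot noise — but not optical nuisances of real data: non-uniform
illumination beyond what the pseudomedian removes, fixed-pattern and drift
artifacts, nanorod orientation-dependent visibility, focus drift, aggregate
labels, or flow-induced transport gradients. Passing the battery therefore
demonstrates the correctness of the computation (detection, linking,
counting, calibration and LOD algebra) under the stated event model, not the
instrument-level performance on real chips; the published attomolar LODs of
the physical system depend on unpublished instrument data and are outside
what desk-scale simulation can certify.
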