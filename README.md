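# spiris

Digital microarray counting for single-particle interferometric reflectance
imaging (SP-IRIS). The package turns raw image stacks of a DNA microarray —
where each captured target molecule is tagged with a plasmonic gold nanorod
and appears as a diffraction-limited spot — into counts of individual
binding events, binding rates, calibration curves and limits of detection
(LOD), down to the attomolar regime. A synthetic scene simulator generates
ground-truth movies and z-stacks so the whole chain is testable without
instrument data.

It is written for assay developers and image-analysis researchers working on
digital (single-molecule counting) biosensors.

## What it computes

**Detection.** Frames are normalized by a per-pixel baseline (the median
across a defocus z-stack for endpoint assays; a robust temporal baseline for
kinetic movies), flattened with a sparse pseudomedian background filter,
scored by zero-normalized cross-correlation (ZNCC) against a particle
kernel, thresholded, and filtered by blob area and area-to-perimeter ratio
so only diffraction-limited (round, PSF-sized) keypoints survive.

**Tracking.** Bound particles are immobile, so detections are linked by
greedy nearest-neighbour association within a small radius; short dropouts
are repaired (gap closing), single-frame positives are discarded, and each
surviving track is one binding event. Counting is *total binding*: a
complex that binds and later debinds still counts, so cumulative curves are
non-decreasing.

**Quantification.** For a kinetic assay the binding rate `r` (events/hour)
of each spot is the OLS slope of its cumulative curve. At low concentration
the rate follows the diffusion-limited sheet-density law

    r(c) = k (c / c_ref)^(2/3)        (slope 0.67 on log-log axes)

The kinetic LOD is the concentration where the theoretical-slope line fitted
through the double-log points crosses `blank mean + 3 SD`, bracketed by the
crossings of the free best-fit line and of the steepest slope consistent
with the data. The endpoint LOD is the classical `3.3 sigma / slope` on the
linear response scale. `molarity_copies` converts molarities to absolute
copy numbers (10 aM in 0.2 mL is 1204.4 copies).

## Worked example

```python
import numpy as np
from spiris import (SimulationConfig, BlankStats, lod_kinetic,
                    make_calibration_dataset, molarity_copies, planted_lod)

config = SimulationConfig(rng_seed=42)          # study conditions
ds = make_calibration_dataset(config, replicates=16, blank_replicates=16)
means = ds.mean_rates()
blank = BlankStats.from_samples(ds.blank_rates)
results = lod_kinetic(means["concentration"], means["rate_mean"], blank)
print(results.summary())
print(f"planted LOD: {planted_lod(config):.3g} M")
print(f"copies at LOD in 0.2 mL: "
      f"{molarity_copies(results.lod.lod, 0.2e-3):.0f}")
```

Output:

```
Kinetic calibration (double-log rate vs concentration)
==========================================================
points (positive rates)                5
free slope                        0.6637
free slope 95% CI           [0.6583, 0.6691]
free intercept                   12.1920
theoretical slope                 0.6667
theory-line intercept            12.2333
blank threshold (events/h)         8.398
LOD (molar)                    1.087e-17
LOD interval (molar)        [1.055e-17, 1.115e-17]
extrapolated                        True
planted LOD: 1.02e-17 M
copies at LOD in 0.2 mL: 1309
```

Reading it: the free slope of the double-log calibration (0.664) matches the
theoretical 2/3 scaling; the detection threshold set by the blank spots
(mean + 3 SD = 8.4 events/h) intersects the theory line at 10.9 aM, in
agreement with the 10.2 aM LOD planted by the simulation conditions, and
`extrapolated` flags that this crossing lies below the lowest measured
concentration (100 aM), exactly as for a real calibration whose LOD is
extrapolated below the dynamic range.

The same chain runs at image level — rendering movies, detecting and
tracking particles — via `spiris.pipeline.run_kinetic_calibration`, or from
the shell:

```sh
spiris report --config run.json --seed 1   # simulate -> detect -> track -> quantify
```

which writes `stack.tif`, `detections.csv`, `tracks.csv`, `event_log.csv`,
`rates.csv` and `calibration_report.json` (all stamped with the config hash
and seed) into the configured output directory.

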