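# angioquant

Quantitative image analysis for endothelial-cell biology: how coordinated
are the cells of a monolayer, how regular is a developing vascular plexus,
how does a marker fall off with distance from the sprouting front, how fast
does a junctional protein turn over, and how to score junction images
blindly without fooling yourself.

The package bundles five small pipelines that are usually re-implemented ad
hoc for every vascular-biology study, together with synthetic-data
generators that emit known ground truth, so every pipeline ships with
parameter-recovery tests.

## What it computes

**Monolayer coordination** (`angioquant.coordination`).  Each cell's
orientation is proxied by the long axis of its nucleus — fitted as the
moments-equivalent ellipse after segmentation — which is a *nematic*
quantity (θ and θ + π are the same axis).  Two nuclei are compared with the
alignment score

&nbsp;&nbsp;&nbsp;&nbsp;*s*(θ₁, θ₂) = cos 2(θ₁ − θ₂),

which is 1 for parallel, 0 at 45°, −1 for perpendicular axes, and averages
to exactly 0 for independently random orientations.  Binning the score of
every pair of nuclei by centroid distance yields a coordination curve:
elevated short-range values that decay to zero reveal locally aligned
streams and swirls in an otherwise disordered monolayer.

**Plexus regularity** (`angioquant.plexus`).  A binary vessel mask encloses
*loops*: bounded connected components of the non-vessel area (border-
touching lacunae are open, not loops).  Regularity is the sample SD of loop
area and of loop circularity 4πA/P² across the cohort; vessel density is
the vessel-pixel fraction of the field.  Loops under 86 µm² are treated as
segmentation artifacts and excluded.

**Front gradients** (`angioquant.front_gradient`).  Marker intensity is
normalised by its mean outside the vessel mask (making the result
detector-gain invariant, extravascular level ≡ 1), every intravascular,
non-arterial pixel gets its exact Euclidean distance to the sprouting-front
mask, and the normalised intensity is averaged in 15 µm distance bins from
0 to 500 µm.  Replicate curves aggregate unweighted (mean ± SEM across
curves).

**Photoconversion turnover** (`angioquant.flap`).  A fluorescence-loss-
after-photoconversion ROI trace is background-subtracted, bleach-corrected
(single-exponential fitted on a fixed-cell control), and normalised so the
pre-conversion mean is 0 and the first post-conversion frame is 1.  The
plateau of the resulting curve is the immobile fraction *f*; the time at
which the smoothed curve first crosses (1 + *f*)/2 — the midpoint of the
mobile span — is the redistribution half-time.

**Blinded patch scoring** (`angioquant.junction_patch`).  Junction images
are tiled into (16 µm)² patches presented in random order under anonymous
names; the shuffled manifest is the blinding key.  Scored labels
(morphology: straight / thick / thick-to-reticular / reticular / fingers;
turnover: high / intermediate / low) are de-blinded through the manifest
and summarised as marginal percentages and a morphology × turnover
crosstab.  An optional quantitative turnover score (retained pulse label ÷
total surface label over junction pixels) is provided for two-channel
pulse-chase images.

## Worked example

```python
import numpy as np
from angioquant.synthetic_data import (NematicFieldSpec, FlapTraceSpec,
                                       gen_nematic_field, gen_flap_trace)
from angioquant.coordination import nuclei_from_image, coordination_curve
from angioquant.flap import analyze

# A monolayer whose nuclear orientations are correlated over ~100 um
spec = NematicFieldSpec(n_nuclei=300, field_size=1000.0,
                        correlation_length=100.0, orientation_noise=0.15,
                        seed=42)
truth, image = gen_nematic_field(spec)
records = nuclei_from_image(image, min_area=20, max_area=1000,
                            expected_minor_axis=10.0)
curve = coordination_curve(records, bin_width=25.0, max_distance=500.0)
print(f"segmented {len(records)} of {len(truth)} nuclei")
for lo, hi, m, c in zip(curve.bin_edges[:-1][:4], curve.bin_edges[1:][:4],
                        curve.mean_alignment[:4], curve.pair_count[:4]):
    print(f"  {lo:4.0f}-{hi:4.0f} um: alignment {m:+.3f}  ({c} pairs)")

# A photoconversion trace with 30% immobile protein and 90 s half-time
tspec = FlapTraceSpec(immobile_fraction=0.3, half_time=90.0,
                      bleach_rate=1e-3, noise_sd=10.0, seed=7)
trace, control = gen_flap_trace(tspec)
est = analyze(trace, control)
print(f"immobile fraction {est.immobile_fraction:.3f}, "
      f"half-time {est.half_time:.1f} s")
```

prints

```
segmented 300 of 300 nuclei
     0-  25 um: alignment +0.928  (51 pairs)
    25-  50 um: alignment +0.870  (280 pairs)
    50-  75 um: alignment +0.760  (421 pairs)
    75- 100 um: alignment +0.699  (546 pairs)
immobile fraction 0.301, half-time 88.8 s
```

Nearby nuclei are strongly aligned (≈0.93 within 25 µm) and the alignment
decays with distance, as built into the generator; the turnover estimates
land on the generator's true values (0.3, 90 s) to within the noise.

Every pipeline is also exposed on the command line
(`angioquant --help`): `simulate`, `coord`, `plexus`, `gradient`, `flap`
and `patch` subcommands read TIFF/PNG images and CSV traces and write CSV
tables plus a plain-text run log (seed, parameters, inputs) beside each
output.

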