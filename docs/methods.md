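# Methods

This note records the models behind each pipeline, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Conventions

Images are row-major 2D arrays with the origin at the top-left; x is the
column index, y the row index.  Pixels are isotropic; the µm-per-pixel
calibration is supplied by configuration (TIFF resolution tags are only
cross-checked, with a warning on >1% disagreement, because metadata
dialects are unreliable).  All downstream quantities — distances, areas,
bin edges — are in µm / µm².  Every tunable parameter below is exposed
through `RunConfig` and logged with each CLI run.

## Monolayer coordination

Cell orientation is proxied by the nucleus long axis.  Orientations are
nematic (axes, not vectors): θ ∈ [0, π), with θ and θ + π identified.  The
pairwise score is s = cos 2Δθ, the unique smooth nematic-invariant score
taking the anchor values 1, 0, −1 at Δθ = 0°, 45°, 90°.  Its expectation
under independent uniform orientations is exactly 0, so a flat curve at 0
is the null; 1 means global parallel order.  The score of every unordered
pair of nuclei within `max_distance` is averaged in half-open distance
bins of `bin_width`.

* `bin_width` = 25 µm, `max_distance` = 1000 µm by default.  The bin width
  is a compromise: narrower bins resolve the decay of short-range order but
  thin out the pair counts per bin.  Both are config-exposed.
* A pair at exactly `max_distance` is excluded (half-open convention).
* Pairs never cross images; multi-image experiments aggregate per-image
  curves with pair-count weighting (`aggregate_curves`).
* Bins with zero pairs report NaN, never 0 — 0 is a meaningful value here.
* Records are internally sorted into a canonical order before accumulation
  so the curve is bit-identical under permutation of the input.

Segmentation is Gaussian smoothing (σ = 1 px) → Otsu threshold → hole
filling → watershed split of touching nuclei seeded from maxima of the
(lightly smoothed) Euclidean distance transform, with a minimum seed
separation of half the expected nucleus minor axis → area filter →
border-region exclusion.  Otsu was chosen because nuclear stains of
confluent monolayers are bimodal and high-contrast; smoothing the distance
transform before peak finding prevents elongated nuclei from seeding twice
along their medial ridge.  Border exclusion applies to segmentation only:
externally supplied record tables are used as given.

The ellipse fit uses second central moments of the pixel set with the
1/12-pixel self-covariance correction (the moments of a unit-square pixel
footprint), so axis lengths are unbiased for small regions; orientation is
the major-axis angle to the image x-axis, folded into [0, π).  Degenerate
(collinear) regions clamp the minor axis to one pixel with a warning.

## Plexus regularity

Loops are connected components of the vessel-mask complement that do not
touch the image border, using 4-connectivity for background against
8-connected vessels (the standard complementary pairing that avoids
counting a diagonal vessel crossing as leaky).  Components under
`min_loop_area` = 86 µm² are treated as thresholding artifacts.  Border
lacunae are not closed loops and are excluded.  Regularity = sample SD
(n − 1) of loop area and of circularity; with fewer than two loops the SDs
are reported as undefined, never 0.  Vessel density is vessel pixels over
all field pixels.

Circularity is 4πA/P² clamped to [0, 1].  The perimeter P is the arc
length of the marching-squares contour after smoothing the contour
coordinates with a periodic Gaussian (σ = 1.5 vertices).  The raw contour
overestimates smooth boundaries by the staircase factor (a rasterized disc
would score ≈ 0.91–0.93), while Crofton-type estimators underestimate
axis-aligned straight edges by ~6% (inflating an axis-aligned 10:1
rectangle's circularity by ~12%).  The smoothed contour keeps a rasterized
disc within ~1% of circularity 1 and an axis-aligned 10:1 rectangle within
~4% of its analytic value, at every orientation we tested.  Regions too
small to produce a contour fall back to the Crofton estimate.

Vessel segmentation is a global threshold (Otsu by default; fixed-value
and percentile methods selectable), a closing with a 1 px disk, and
removal of vessel fragments under 10 µm² (speckle).

## Front gradients

The front is supplied as a mask drawn upstream; no automatic front
detection is attempted.  Normalisation divides the raw marker channel by
the mean over *all* extravascular pixels of the field, so the profile is
invariant to detector gain and the extravascular level is 1 by
construction.  Distances are the exact Euclidean distance transform to the
nearest front pixel, scaled to µm.  Eligible pixels are vessel ∧ ¬artery
within `max_distance`; binning is half-open, 15 µm wide, 0–500 µm by
default.  Replicates aggregate unweighted — each curve counts once — with
SEM = SD/√n computed only in bins where every replicate has data; a single
replicate has an undefined (NaN) SEM.  The pipeline operates on the raw
channel; an optional constant-background subtraction can be applied
upstream if needed.

## Photoconversion (FLAP) turnover

Model for the background-free, bleach-free, normalised post-conversion
signal: I(t) = f + (1 − f)·2^(−t/t½), t from the first post-conversion
frame; f is the immobile fraction, t½ the redistribution half-time of the
mobile pool.  Processing order:

1. per-frame background subtraction (a negative plateau is flagged);
2. bleach correction: divide by exp(−k_b·t) with k_b fitted as a single
   exponential on a background-subtracted fixed-cell control.  One control
   trace cannot constrain a richer bleaching model, hence
   single-exponential;
3. normalisation: affine map sending the pre-conversion mean to 0 and the
   *single* first post-conversion frame to 1 (an averaging option over the
   first frames exists for noisy data but is off by default);
4. estimation: f = mean of the last 10% of frames (at least 5), clamped to
   [0, 1]; t½ = first time the smoothed curve crosses (1 + f)/2, linearly
   interpolated between frames.  Defining the half-time on the mobile span
   is the standard convention for recovery/loss curves.  A curve that
   never drops below its midpoint (e.g. fully immobile) has an undefined
   half-time, reported as such.

Defaults: 10 s frames, 15 min monitoring, smoothing window 5 frames
(centered moving average, shrinking at the edges), plateau window 10%.
For noiseless data a smoothing window of 1 removes the small (~2%)
late-crossing bias a 5-frame window introduces on convex curves.  The
estimates are invariant under affine gain/offset of the raw intensities
because subtraction and normalisation cancel them.  Traces span many
half-times by design; a warning fires when coverage drops below 3
half-times, where the plateau becomes unreliable.  Manual quality control
(junctions that moved or remodelled) is carried as a boolean flag per
trace, not automated.

## Blinded patch workflows

Fields are tiled into (16 µm)² patches ((160 µm)² fields give exactly
100).  Only the presentation order is randomised; the anonymous names are
position-free, and the manifest (name ↔ image/row/col) is the single
blinding key.  Fields that are not an integer multiple of the patch size
drop the trailing remainder with a warning.  Unknown names and duplicate
labels are hard errors.  Crosstab percentages exclude unscorable/unscored
patches from the denominators and report the excluded count; categories
with fewer than 5 scored patches are flagged as unreliable.

The quantitative turnover score — mean retained pulse-label intensity over
junction pixels divided by mean total surface-label intensity over the
same pixels — is an *extension*, not a replacement for manual scoring.
Its class thresholds (high < 0.35 ≤ intermediate ≤ 0.65 < low on the
retained ratio) were calibrated on the synthetic generator only and should
be re-calibrated for real stains.

## Synthetic data: what it emulates, and what passing tests show

All generators are pure functions of their spec including the seed, and
always emit ground truth beside the rendering.

* **Nuclei fields**: non-overlapping filled ellipses (center distance ≥
  one major axis; binary rendering, no anti-aliasing so segmentation tests
  are deterministic).  The orientation field is built by smoothing complex
  white noise of the *doubled* angle with a Gaussian of width ξ and
  halving the argument — smoothing θ directly would wrap at π — then
  adding per-nucleus Gaussian jitter of SD κ.  ξ = 0 degenerates to i.i.d.
  uniform orientations, ξ = ∞ to a single global director.  Defaults:
  18 × 10 µm nuclei (typical cultured endothelial nuclei), κ = 0.15 rad.
  One realisation of a correlated field retains long-range order of
  magnitude ~(2ξ/L)² through the shared director; fields several times ξ,
  or averages over independent fields, are needed for the far tail of the
  coordination curve to sit at the noise floor.
* **Vessel networks**: Voronoi tessellation of a triangular lattice whose
  spacing sets the mean loop area, with sites displaced by Gaussian noise
  of SD = `perturbation` × spacing; edges dilated to the vessel width.
  The outermost 1.5 lattice bands are cropped so only bulk loops remain.
  Ground-truth loops are extracted *from the rendered mask itself*, so
  generator and analyzer share one geometric definition and disagreements
  measure segmentation, not rasterization.
* **Front gradients**: intravascular intensity
  E·(B + (A − B)·e^(−d/λ)) with extravascular mean E, plus optional
  additive Gaussian noise.
* **FLAP traces**: raw ROI = (background + S·I(t))·e^(−k_b·t_global) +
  noise, with t_global counted from acquisition start (pre-conversion
  frames included) — the way a microscope actually bleaches; the paired
  fixed-cell control shares k_b and has I ≡ 1.
* **Pulse-chase patches**: one Bézier junction curve per patch, dilated to
  a few pixels; the retained ratio per patch is drawn from one of three
  Gaussians (means 0.15 / 0.50 / 0.85, SD 0.05 — 7 SD separation) chosen
  by the requested class mix.

None of the generators model optics: no point-spread function, no Poisson
shot noise, no uneven illumination, no tissue autofluorescence, no
overlapping or dividing nuclei.  Passing recovery tests therefore
demonstrate the *estimators* are correct and unbiased under the stated
noise, not that segmentation is robust to every real-microscopy artifact;
on real data the segmentation steps (thresholds, watershed seeds, speckle
sizes) are the parameters to revisit first.

## Problem sizes

The test suite exercises the pipelines at sizes chosen to make the
statistical assertions sharp but cheap: coordination recovery uses three
independent 2000 µm fields of 800 nuclei (aggregated, mirroring how
multi-experiment curves are combined); the random-monolayer null uses
10,000 nuclei (5 × 10⁷ pairs, computed in blocked accumulation at O(chunk
× n) memory); plexus agreement uses ~60-loop networks; FLAP recovery uses
20 noise seeds per parameter combination.

## Known limitations

* Only isotropic pixels; anisotropic input is rejected.
* No z-stacks beyond upstream max-projection; no registration; no OME-XML.
* Loop topology is purely 2D; a vessel crossing in 3D reads as a closed
  loop split.
* The coordination curve has no edge correction: bins near the field
  diagonal hold few, geometrically biased pairs (they are reported with
  their pair counts so downstream users can filter).
* The FLAP plateau estimator assumes the acquisition spans several
  half-times; short traces bias f upward.
* Automated junction-morphology classification is out of scope; the patch
  module manages blinding and bookkeeping around a human scorer.
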