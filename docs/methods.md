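# Methods

## The measurement problem

After axotomy, a neurite field degenerates from a small number of long,
bright, continuous structures into a large number of small, still-bright
fragments. Total fluorescence is nearly conserved (fragments are
membrane-enclosed and retain calcein/RFP), so summary intensities are blind
to degeneration; the informative signal is the object-size distribution of
the segmented image. `axoquant` quantifies that signal with two normalized
statistics computed from ordinary particle analysis, plus an area-based well
QC.

## Image conditioning chain

Order is fixed: background subtraction → unsharp mask → median filter. All
internal arithmetic is float64; 8-bit, 16-bit and floating input rasters are
accepted. All windowed filters replicate edges (a zero pad would create a
dark rim that the downstream mean threshold would segment).

**Rolling-ball background subtraction** (`background_radius_px`, default
50 px for 1376 × 1104 px fields). The background is the grayscale opening of
the image with a ball structuring element: erosion then dilation with the
hemispherical height map `h(dx,dy) = √(r² − dx² − dy²)` on the disk
`dx² + dy² ≤ r²`, clipped below at 0. This is the exact classical operator —
no downscaling shortcut — so it is reproducible and testable against a
brute-force opening; its cost is O(pixels · r²). The opening is
anti-extensive, so the output never exceeds the input, and a flat field maps
to zero. Note the ball penetrates narrow plateaus slightly (by
`r − √(r² − w²/4)` for width w), so a 3-px-wide feature at height Δ above
flat background retains Δ minus a few hundredths, not Δ exactly.

**Unsharp mask** (`unsharp_weight` w = 0.6, `unsharp_radius_px` σ = 2 px):
`(I − w·G_σ I)/(1 − w)`, Gaussian truncated at 4σ (≤ 1e−4 of kernel mass
lost), negatives clipped at 0. The renormalization makes a flat field a
fixed point and w = 0 the exact identity. w is the mask weight in the
convention of the classical implementations that call it "strength"; since
other conventions exist, it is an explicit parameter.

**Median filter** (`median_radius_px` = 1): circular neighborhood
`dx² + dy² ≤ r²`; for radius 1 this is the 5-pixel cross (circular-kernel
convention), not the 3×3 square.

## Segmentation and particle analysis

The threshold is the arithmetic mean of all pixel intensities of the
conditioned image; foreground is strictly above it (neurites are bright on
dark). The mean method needs no parameters and is invariant under positive
affine intensity rescaling, but it presumes the image contains foreground:
on a featureless field it segments noise (see Limitations).

Connected components use 8-connectivity by default (4 available). Objects
with area ≥ 10 µm² are kept — the boundary is inclusive ("10–Infinity"
semantics) — with labels preserved, no relabeling. The µm/px calibration is
a required input with no default; the tests and simulator use 0.5 µm/px as a
convention. Edge-touching particles are included; holes are not filled.

Per image: object count, mean object size (µm²; undefined — propagated as
NaN — for object-free images), total object area (the "neurite-covered
area").

## Normalized statistics

With reference statistics from an intact set and a fully degenerated set
(recorded > 18 h after the cut):

* `fragmentation(count) = (count − count_intact)/(count_cut − count_intact)·100`
  — strictly increasing in the count, 0% at the intact anchor, 100% at the
  degenerated anchor;
* `integrity(size) = (log size − log size_cut)/(log size_intact − log size_cut)·100`
  — log-transformed for variance stabilization (object sizes span orders of
  magnitude); base-free since only ratios of log differences enter; natural
  log used internally.

Neither statistic is clamped: counts below the intact reference or sizes
above it legitimately score < 0% fragmentation or > 100% integrity. Both are
invariant under a common positive rescaling of all areas (a calibration
change).

Aggregation is per-image-then-mean by default: reference and sample
statistics are means of per-image counts / per-image mean sizes / per-image
total areas, matching an acquisition design of n fields per condition. A
pooled mode (grand total area ÷ grand count) is provided as an alternative;
the two differ when per-image object counts vary strongly. Object-free
images count toward counts and areas but are excluded from size means.

Well QC: `area_ratio = total_area_sample / area_intact`, passing when
strictly above 0.70. The rationale: mass conservation of fragments means
degeneration itself does not reduce covered area much, so a low ratio flags
a defective well (detachment, washout, focus) rather than degeneration.

## Synthetic data generator

The generator emulates the content of neurite-only-culture micrographs: the
somata dome lies outside the frame, so tracks enter from one border and run
roughly radially.

* **Geometry** — `n_tracks` random-walk polylines start on the bottom
  border, headed away from a virtual dome center below the field, with
  per-step angular noise `curvature_jitter` (default 0.06 rad / 2 px step).
* **Photometry** — tracks are ridges of Gaussian cross-section
  (`track_width_px` σ = 1.5 px, peak `track_intensity` = 800) rendered by
  splatting line mass `I·√(2π)·σ` per px and blurring; background is a level
  (150) plus a linear row gradient (0.05/px) plus i.i.d. Gaussian noise
  (σ = 15); 16-bit clipping happens only on export. Intensities are
  arbitrary units chosen to resemble a mid-range 16-bit camera with neurites
  well above background (SNR ≈ 50 at the ridge peak).
* **Degeneration model** — candidate breakpoints are drawn per track from a
  Poisson process along arclength at rate 0.04/µm with i.i.d. uniform marks;
  at degree f the candidates with mark ≤ f are active (thinning), which
  makes breakpoint sets nested in f for a fixed seed: a time-lapse
  accumulates breaks and never heals them, and f = 0 has none. A ±15 µm
  window around each active breakpoint is replaced by a chain of Gaussian
  beads (`bead_spacing_um` = 10, `bead_radius_um` σ = 1.5). The rate/window
  pair was chosen so the converted fraction of a track,
  `1 − exp(−2·15·0.04·f)`, grows smoothly over the whole f range rather than
  saturating early, keeping object count and mean size monotone in f.
* **Mass conservation** (default on) — each converted stretch's bead masses
  sum exactly to the line mass of the neurite it replaced, so the integrated
  above-background fluorescence is conserved up to rasterization (< ±10%),
  and the pipeline-measured covered area of a fully fragmented field stays
  comfortably above the 70% QC bound.
* **Kinetics** — a logistic maps hours post-axotomy to f through the anchors
  f(onset) = 0.1 at 7 h (first visible signs of degeneration, within the
  observed 6–8 h window) and f = 0.95 at 18 h (degeneration strictly above
  the 90% mark); f(0) ≈ 0.004 and f(24 h) ≈ 0.997. Both anchors are exposed
  in `KineticsParams`.

What the generator does **not** emulate: out-of-focus light and PSF
anisotropy, photobleaching, stage drift, neurite crossings with varying
intensity, debris, uneven staining, tubulin aggregates. Passing tests on
synthetic data therefore demonstrate the pipeline's algorithmic correctness
and its sensitivity to the count/size signature of fragmentation — not
robustness to every real-world artifact.

## Problem sizes

The exact ball opening costs O(pixels·r²), which at full scale
(1376 × 1104, r = 50) is minutes per image on one CPU. Simulation studies
(tests and `scripts/acceptance.py`) therefore run a quarter-scale preset:
344 × 276 px fields, 15 tracks, background radius 12 px (the radius scaled
with the field, keeping it ≫ neurite width so the background estimate is
unaffected). Every quantity reported from these studies — fragmentation,
integrity, area ratios — is a normalized percentage and scale-free; the
full-scale defaults remain on `FieldParams`/`RunConfig` for production use.
Study sizes: 10 fields for the area-conservation study, 10 wells × 6 time
points for the kinetics study, 20 seeds × 5 degrees for metric recovery in
the test suite.

## Numerical and degenerate-input choices

* Constant images threshold to an empty foreground (warning, not an error);
  empty object tables yield count 0, total area 0, mean size NaN.
* Integrity of a NaN size is NaN; integrity of a non-positive size is a
  domain error; references violating `count_cut > count_intact` or
  `size_intact > size_cut > 0` raise a reference-validity error naming the
  inequality.
* The QC comparison is strict (> 0.70), as is the mean threshold (> mean).
* Seeds: geometry, background noise and breakpoint candidates use separate
  deterministic streams derived from the user seed, so the same field can be
  re-rendered at any degeneration degree bit-reproducibly.

## Known limitations

* **Mean thresholding of empty fields.** On a field with no neurites the
  mean threshold sits inside the noise distribution; ~45% of pixels segment
  as foreground, near the 8-connectivity percolation point, producing a few
  large noise clusters (1–8 per quarter-scale field). The area QC against an
  intact reference does not catch this case (noise area can rival neurite
  area); empty wells must be excluded upstream. This is a property of the
  mean method itself, faithfully reproduced.
* Touching fragments are not split (no watershed), so fragmentation
  saturates when beads merge at high density.
* No neurite tracing or length statistics; no multi-channel, z-stack or
  deconvolution support.
* Statistical inference across replicates (ANOVA etc.) is out of scope; the
  pipeline emits tidy per-well CSV for external statistics tools.
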