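# axoquant

Observer-independent quantification of axotomy-induced neurite degeneration
from fluorescence micrographs.

When neurites are severed from their cell bodies (axotomy), they undergo
Wallerian-like degeneration: initially smooth, continuous neurites bead up
and break into many small membrane-enclosed fragments. Because the fragments
keep their dye (calcein or cytosolic RFP), total fluorescence barely changes
— what changes is the *structure* of the image: many more, much smaller
objects. `axoquant` turns that observation into two normalized statistics
computed from plain particle analysis, so that degeneration can be compared
across wells, runs and interventions without an observer in the loop.

The package also ships a synthetic neurite-field simulator (radial
Gaussian-ridge tracks, beads-on-a-chain fragmentation with fluorescence-mass
conservation, logistic degeneration kinetics) so the entire pipeline can be
exercised and validated end-to-end with no microscope data.

## Method

Each micrograph passes through a fixed conditioning chain:

1. rolling-ball background subtraction (ball radius 50 px, implemented as
   the exact grayscale morphological opening with a ball structuring
   element),
2. unsharp mask (weight w = 0.6, Gaussian radius 2 px):
   `(I − w·G_σ I) / (1 − w)`,
3. circular median filter (radius 1 px, the 5-pixel cross),

then is binarized at its arithmetic-mean intensity, and connected components
(8-connectivity) with area ≥ 10 µm² are retained. Per image this yields the
object count, the mean object size, and the total object area (the
"neurite-covered area").

Against a pair of reference image sets — *intact* neurites and *fully
degenerated* neurites (recorded > 18 h after the cut) — two statistics are
computed:

```
Fragmentation [%]        = (count_sample − count_intact) / (count_cut − count_intact) · 100
Integrity [% of intact]  = (log size_sample − log size_cut) / (log size_intact − log size_cut) · 100
```

Fragmentation is anchored at 0% (intact) and 100% (fully degenerated);
integrity at 100% (intact) and 0% (degenerated), with sizes logarithmized
for variance stabilization (the base is immaterial). Neither is clamped.
A well is evaluable only if its neurite-covered area exceeds 70% of the
intact reference area (strict); this QC exploits the fact that fragments
stay fluorescent, so a large area drop signals a bad well, not degeneration.

## Worked example

Simulate a small axotomy time course (two fields per time point,
quarter-scale 344 × 276 px fields) and quantify it against its own 0 h
(intact) and 24 h (fully degenerated) wells:

```bash
axoquant simulate --out demo --seed 42 --times 0,8,18,24 --n-fields 2 \
    --height 276 --width 344 --n-tracks 15
# edit demo/config.yaml: background_radius_px: 12.0   (radius scaled to the field)
axoquant quantify demo --config demo/config.yaml
```

```
well_id  time_h  n_images  count_sample  size_sample_um2  total_area_um2  fragmentation_pct  integrity_pct  area_ratio  qc_pass
t000.0h     0.0         2           9.0       376.008117        3167.875           0.000000     100.000000    1.000000     True
t008.0h     8.0         2          34.0        94.897078        3217.625          35.714286      37.094316    1.015705     True
t018.0h    18.0         2          76.5        43.469263        3326.500          96.428571       1.422996    1.050073     True
t024.0h    24.0         2          79.0        42.136272        3331.375         100.000000       0.000000    1.051612     True
```

Reading the table: at 0 h the field holds a few large objects (9 per image,
~376 µm² each) — intact neurites. By 18 h the same field has broken into
~77 objects of ~43 µm², scoring 96% fragmentation and ~1% integrity, while
the covered area (`area_ratio` ≈ 1.05) is unchanged — fragments conserve
their fluorescence, so every well passes QC. The reference wells themselves
score exactly 0%/100% (t = 0 h) and 100%/0% (t = 24 h) by construction of
the normalization. Results are written as `wells.csv`, `images.csv` and a
`run.json` provenance record carrying the configuration hash stamped on
every row.

The same analysis is available as a library (`axoquant.quantify_image`,
`axoquant.fragmentation`, `axoquant.generate_timecourse`, …); see the
docstrings and `docs/methods.md`.

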