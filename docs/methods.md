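# Methods

## Problem and approach

Histological stains separate infarcted/fibrotic myocardium from viable tissue
by color, not by intensity alone, so the segmentation problem reduces to
per-pixel rules on raw RGB values. `scarquant` deliberately implements raw-RGB
thresholding — no color deconvolution, no learned segmentation — because the
color contrast each stain produces is large enough that simple rules with
user-adjustable thresholds are transparent, fast and auditable. The pipeline
is: tissue masking → stain-specific infarct rule → mask post-processing
(crop, dilate, artifact removal) → pixel-count quantification (relative size,
area, serial-section volume, fibrosis fraction).

## Tissue mask

A pixel is tissue when min(R, G, B) < `background_white_min` (default 230):
slide background is near-white, so all three channels are high; any stained
pixel has at least one suppressed channel. Post-processing keeps connected
components of at least 5% of the largest component's area (drops dust and
noise speckle) and fills holes (a ventricular lumen is counted as background
only if it touches the image border, otherwise filled; the "entire section"
denominator used throughout is the tissue-mask pixel count, background
excluded). The 230 default sits >5σ below the synthetic background (245) at
the default noise level and well above every tissue palette channel minimum.

## Stain rules

All rules are evaluated only inside the tissue mask; the infarct mask is a
subset of the tissue mask by construction.

**MTS.** Infarct iff R ≤ `r_limit` (default 150) and B/R ≥ `br_ratio_min`
(default 1.2). The anchors are the palette examples: infarct R ≈ 41, normal
muscle R ≈ 251; 150 splits them with >13σ margin at noise sd 8. The B/R
ratio rejects faint non-blue pixels that pass the R test alone. At R = 0 the
ratio is treated as +∞ when B > 0; the all-zero black pixel is classified
non-infarct (degenerate input, not blue).

**TTC.** Infarct iff the sample standard deviation (n−1 denominator, a
documented and configurable choice) of the three channel values is ≤
`std_max` (default 20). Off-white infarct (133, 136, 134) has stddev ≈ 1.5;
deep-red viable tissue (187, 69, 61) has ≈ 70.9. The rule must be gated by
the tissue mask because white background is also near-achromatic; the
Phthalo-blue perfused region, when present, has a dominant B channel and a
large stddev, so it is excluded automatically. With per-channel noise sd 8,
P(sample std of an achromatic pixel > 20) ≈ e^−6.25 ≈ 0.2%, so the default
tolerates realistic noise.

**PSR.** With mean_GB = (G+B)/2, infarct iff R − mean_GB ≥ `thd`. The margin
is computed in exact integer arithmetic (2R − G − B ≥ 2·thd) so half-unit
values never flip through float rounding. The condition is implemented as the
margin test only: a literal disjunction "R > mean_GB or margin ≥ thd" would
make thd inert (the first clause subsumes the second for any thd ≥ 0), which
contradicts thd's role as the user-set extraction threshold. Default thd =
60: the palette margins are 104 (infarct 240, 129, 143) and 21.5 (normal
204, 191, 174), and the margin noise sd at channel noise 8 is 8·√1.5 ≈ 9.8,
so 60 — near the midpoint — keeps both classes ≈4σ from the boundary. A
lower value such as 40 leaves pale normal tissue within 2σ of
misclassification and measurably inflates the infarct fraction on noisy
sections.

**H&E.** The infarct differs mainly in green (≈174 vs ≈99), too subtle for a
direct threshold, so a two-step transform reveals it first. Step 1: any
channel above `r_limit` (default 200) is zeroed, the pixel's other channels
unchanged — this knocks out the dominant red of normal eosin-stained tissue.
Step 2: if R < G or B < G the pixel keeps only its green (R := 0, B := 0);
otherwise all channels are zeroed. Pixels failing the condition are
suppressed to black — the transform's output is a visualization and the
downstream mask depends only on which pixels retain green. Normal myocardium
retains sparse, strong green speckle, so the classifier then keeps only
large, dense green areas: candidates are grouped by a morphological closing
(disk radius 3 px) and components whose *green pixel count* is below
`min_area_frac` (default 0.1%) of the tissue area are dropped. Component size
is measured on the candidate pixels rather than the closed footprint so that
speckle chains the closing happens to bridge still count as small; retained
pixels are the original candidates, so closing never adds pixels to the mask.
8-connectivity is used for components throughout the package.

## Mask post-processing

Cropping zeroes pixels outside a rectangular ROI without resizing, so all
masks stay aligned to their image. Dilation uses a Euclidean disk (radius 1 =
the 5-pixel plus shape); because dilation inflates area, quantification
counts the undilated mask unless the user passes `--count-dilated`, and the
RunRecord states which was used. Artifact removal sets user-supplied
exclusion ROIs (e.g. a bubble over a TTC section) to false and drops
components below a minimum area; it is idempotent.

## Quantification

Units: pixel size Px in µm/pixel, thicknesses in µm, areas in mm²
(Px²·count/10⁶), volumes in mm³ (area·thickness/10³). Relative infarct size
is 100·∑P_s/∑P_t %. For serial-section volumes each stained section (h1)
plus its removed slab (h2) contributes A_si·(h1+h2); this per-section gap
policy is the default, and `--gaps n-1` instead attributes removed tissue
only between consecutive sections (the two differ by exactly one gap's
volume — the published bookkeeping leaves the last section ambiguous).
Percentages are printed at one decimal in CLI summaries; machine-readable
outputs keep full precision.

**Fibrosis mode** (MTS only) applies the same blue rule per pixel with *no*
minimum-component filtering, because diffuse fibrosis is scattered single
fibers that a size filter would erase, and reports
100·fibrotic/tissue pixels plus an isolated-fibrosis image.

## Synthetic generator

The generator exists so every stage is testable with exact ground truth and
no external data. A section is a near-white background (245, 245, 245), an
elliptical (or annular) tissue region in the stain's normal palette, an
infarct of circular blobs — or a Bernoulli sprinkle at a requested fraction
in diffuse mode — in the infarct palette, optional rectangular "bubble"
artifacts (210, 208, 211: low-stddev, so deliberately misread by the TTC
rule until excluded), and i.i.d. per-channel Gaussian noise (default sd 8,
clipped to [0, 255]). Palettes anchor to the documented example pixels of
each stain so a noise-free fixture sits strictly on the correct side of
every default threshold. H&E fixtures add 1% green speckle in normal tissue
to exercise the density filter, with an 8-px guard band around the infarct
border so the painted truth stays unambiguous. Truth masks are the painted
regions before noise; all randomness flows through one seed.

What the generator does *not* model: stain texture and gradients, partial
volume/mixing at region borders, uneven illumination, faded or over-stained
slides, tissue folds and tears. Passing tests therefore demonstrate that the
rules implement their definitions and are robust to pixel noise around the
nominal palettes — not that the default thresholds are optimal for any
particular scanner or staining batch; thresholds are expected to need
adjustment on real material, which is why every one is a flag.

Stacks sample a 3-D infarct geometry at section mid-depths: a cylinder
(constant cross-section; its analytic volume is the painted cross-section
extruded over the stack depth, which the per-section sum matches exactly) or
a spherical cap of height h_c from a sphere of radius R_s (analytic volume
π·h_c²·(R_s − h_c/3)); cap recovery carries O((pitch/R)²) Riemann error plus
rasterization error, both well inside the 5% validation band at the sizes
used (80 sections of 256×256 px at 5 µm/pixel, R_s = 500 µm, h_c = 900 µm —
sizes chosen to keep the full validation suite fast while leaving
discretization error far below the tolerance).

## Numerical and design choices

- Integer/exact comparisons wherever a threshold could fall on a boundary
  (PSR margin, MTS at R = 0); elsewhere float64.
- 16-bit inputs are rescaled by round(v·255/65535); JPEG is read-only —
  intermediates are always PNG/TIFF so round-trips are lossless.
- Splitting uses row-major, 0-based, half-open [top, bottom) bands on either
  axis, making the partition identity exact; the auto-splitter (projection
  onto the split axis, cuts at background valleys) is a convenience beyond
  the interactive tool it replaces.
- The stain rules are exposed as scikit-learn estimators (stateless `fit`,
  `predict(image) → mask`) so thresholds ride the standard
  `get_params`/`set_params` machinery; nothing is learned from data.

## Known limitations

- Raw-RGB rules inherit the staining-quality sensitivity of the approach:
  weak color contrast degrades accuracy, and thresholds are global per image
  (no local adaptation).
- H&E analysis targets compact infarcts; sparse fibrosis in H&E is
  indistinguishable from the normal green speckle and is out of scope
  (fibrosis mode is MTS-only).
- Volume estimation assumes the removed tissue carries the adjacent
  section's cross-section; no interpolation or 3-D reconstruction between
  sections is attempted.
- Whole-slide pyramidal formats (SVS/NDPI) are not read; export flat
  PNG/TIFF first.
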