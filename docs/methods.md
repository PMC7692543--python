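# Methods

## The measurement model

The unit of analysis is a single-object grayscale image from the
polarised channel of an imaging flow cytometer (one image per detected
particle, 0.33 µm²/pixel at 60X by default). All morphometry is
mask-based:

1. **Object (tight) mask.** The background-separation threshold is
   `min(Otsu, triangle)` with a relative floor `median + 0.05·(max −
   median)`. Otsu alone mis-segments extinction-cross objects (their
   histogram is dominated by dark arm/background pixels and the Otsu
   split lands inside the bright quadrants); the triangle threshold
   tracks the background foot, and the floor keeps the upper tail of
   sensor noise out of the foreground. The thresholded set is then
   dilated (disk, radius 2 px), hole-filled and eroded back — a closing
   with hole-filling in between — so the dark arms and core of a calcite
   cross are absorbed into the plate outline; only the largest
   8-connected component is kept. If the candidate foreground's median
   intensity is less than `contrast_min` (3×) the background median, the
   mask is empty and the object is a non-detection. Every rule is a
   ratio of intensities, so masks are invariant to positive rescaling of
   the image.
2. **Peak mask.** Bright detail is isolated with a white top-hat (image
   minus its grey opening under a disk of radius `detail_radius_um`,
   default 1.7 µm ≈ 3 px). The footprint must sit between the bright-spot
   scale (≤ ~1.3 µm) and the radius of the smallest coccosphere body
   (≥ ~3.4 µm): larger footprints fail to flatten small sphere bodies and
   the whole object becomes one "peak". A pixel is a peak pixel when its
   top-hat prominence is ≥ `spot_to_bg_ratio` (3×) the background level,
   estimated as the median intensity *outside* the tight mask. (The
   in-object median cannot serve as the reference: on a bright
   coccosphere body it would put the threshold above the calcite
   saturation level.)
3. **Range mask.** Peak components are kept iff their physical area lies
   in the closed interval [0.56, 555.56] µm². Component areas are counted
   before any smoothing; connectivity is 8-way throughout, which matters
   for spot counts at diagonal contacts.

Features: equal-area diameter `2·√(n·pixel_area/π)`; circularity
`mean(r)/SD(r)` over boundary-pixel distances to the mask centroid
("variation" read as the population standard deviation — the only
reading that is scale-free and yields the O(10) gate values in use;
boundary pixels are mask pixels with ≥ 1 non-mask 4-neighbour; a zero-SD
boundary returns `inf`, which passes every ≥ gate); spot count; aspect
ratio from the mask's second central moments (minor/major, in (0, 1]);
and Gradient RMS — the RMS Sobel magnitude over the tight mask's
bounding box of the image min-max rescaled to 0–255, divided by 2.5.
That divisor calibrates the score so the conventional focus threshold
(15) separates the generator's in-focus objects (≥ ~22) from σ = 4 px
Gaussian-defocused copies (≤ ~12). The instrument software's own scale
is proprietary; for real exports the focus threshold is configurable and
should be re-checked against a defocused control.

## The gating protocol

Stages run in a fixed order and each object receives exactly one label:
non-detections → `nonbirefringent`; Gradient RMS strictly > 15 or
`unfocused`; aspect ratio strictly > 0.75 or `doublet`; optional bead
windows (diameter × aspect ratio) → `bead`; maximum raw intensity ≥ the
birefringence threshold (default 15 on the 8-bit scale, i.e. ~10 over
the generator's background mean of 5 — in hardware this filter is
optical, so software needs an explicit value) or `nonbirefringent`;
**R1** diameter ∈ [3, 30] µm (closed) and circularity ≥ 10 or
`birefringent_other`; **R2** by bright-spot count. The comparison
conventions (strict for focus/singlet, inclusive for circularity and
spot gates) follow the protocol's published wording. In field mode R2
assigns ≤ 4 → `coccolith`, 5–9 → `review`, ≥ 10 → `coccosphere`; the
review band's upper edge is pinned to `spot_pure_min − 1` so the bands
partition cleanly, resolving the ambiguity that field coccoliths can
reach 10 spots while the pure gate also starts at 10 — the "≥ 10 is
pure" reading wins, and review objects are exported for manual
inspection rather than auto-assigned. In control mode (cultured material
only) the split is ≥ 5 → coccosphere, < 5 → coccolith.

`derive_template` turns control samples into gate bounds: the [min, max]
diameter and minimum circularity of visually confirmed coccospheres, and
the fraction of negative-control (calcite-dissolved sediment) particles
falling inside that region as the contamination estimate.

Population summaries report per-label counts, the coccosphere fraction
of the birefringent population (objects that reached the morphology
gates), size statistics/histogram of the pure coccosphere population,
and an optional event rate (objects/s) when the acquisition time is
known.

## The synthetic generator

The generator emulates the optical classes of a fine-fraction sediment
sample, 8-bit grayscale on 64×64 px canvases (background mean ≈ 5,
calcite peak ≈ 230; intensities are design choices — published images
are qualitative only):

- **Face-on coccolith**: intensity ∝ sin²(2θ) inside the plate disk
  (radial calcite c-axes between crossed polarisers extinguish along the
  polariser axes), with a dark 1 px core and 5% multiplicative speckle.
  The cross centre sits on integer pixel coordinates so the dark arms
  align with pixel rows/columns and the four quadrants stay
  8-disconnected after rasterisation. Tilted plates are foreshortened
  ellipses (axis ratio 0.78–0.92) with a two-lobe pattern.
- **Coccosphere**: a quasi-circular body (intensity ≈ 110, low-relief
  texture clipped to ±6 so body relief stays below the peak threshold)
  whose boundary radius varies by at most `roughness` (default 3%,
  harmonic profile normalised to max |f| = 1). Face-on coccoliths are
  tiled around a ring at 0.64 R as *unresolved* bright spots: at
  0.33 µm²/pixel the extinction cross of a 1–3 µm plate falls below the
  0.56 µm² spot floor, so each face-on coccolith contributes one spot;
  full crosses appear only on isolated larger plates. Rendered spots are
  capped by the ring circumference at a 4.2 px minimum pitch (keeping
  neighbours 8-disconnected), plus one pole-facing spot on crowded large
  spheres; `n_face_on` in the truth table is the rendered spot count.
  Default spheres (6–12 µm, 8–16 coccoliths) produce 5–10 spots — most
  land in the review band, mirroring the observation that even cultured
  coccospheres can show as few as 8 spots.
- **Sediment**: star-polygon fragments with harmonic radial roughness
  normalised to unit RMS (amplitude 0.25–0.45 of the radius, with a
  1.6 px floor so small fragments still rasterise as irregular); the RMS
  normalisation bounds circularity near 1/amplitude ≈ 2–4, safely below
  the R1 gate. Birefringent fragments are bright with smooth internal
  texture; non-birefringent ones share the geometry but stay below the
  birefringence threshold (max 13 < 15).
- **Beads** (1 µm bright disks), **doublets** (two tangent disks,
  aspect ratio ≈ 0.45–0.55) and **defocus** (Gaussian blur, σ increased
  from 3 px until the Gradient RMS falls to the focus threshold).

Calibration pairs follow `cell = intercept + slope·coccosphere + ε`,
with coccosphere diameters uniform on 3–16 µm and `ε ~ N(0, σ)`; σ can
be set directly or derived from a target R² via
`σ² = slope²·var(x)·(1 − R²)/R²`. Default operating point: slope 0.836,
R² 0.956.

What the generator does *not* emulate: real calcite crystallography and
Mueller-matrix polarisation optics, species-specific coccolith
morphology, multi-layered coccospheres, partial dissolution/overgrowth,
tintinnid loricae and foraminifer fragments whose shapes can approach
coccosphere circularity, and the instrument's proprietary feature
scales. Passing tests therefore demonstrate the internal consistency and
separability of the protocol under its stated assumptions, not its
error rates on instrument data; the gate thresholds are configurable
precisely because the Gradient RMS and peak-detection scales must be
re-calibrated per instrument export.

## Calibration statistics

`fit_calibration` is ordinary least squares (statsmodels), with the 95%
slope CI from the t distribution and optional per-species sub-models;
fits without intercept are supported (the published pooled shortcut,
cell = 0.836 × coccosphere, is exposed as the `pooled_placolith_model()`
preset with intercept 0 — documented as an approximation, since the
published regressions do not state whether an intercept was included,
and the package defaults to fitting one). The "± 0.01 µm" attached to
the dimensionless pooled slope is read as the CI half-width 0.01.
Slope heterogeneity between species uses the SSE decomposition
`F = [(SSE_c − SSE_s)/(k−1)] / [SSE_s/(n−2k)]` comparing the
common-slope (separate intercepts) model against separate slopes; a
statsmodels interaction-model ANOVA serves as the independent
cross-check in the tests. Prediction intervals use the closed OLS form
`t·s·√(1 + 1/n + (d − x̄)²/Sxx)` (uncentred variant for no-intercept
fits). Two-sample diameter comparisons default to Student's
pooled-variance t-test, with Welch available.

## Problem sizes and numerical choices

The test suite runs the full pipeline on a 10,000-object gallery
(64×64 px objects; ~30 s) for end-to-end recovery, 1,000 random grids
for oracle equivalence, and 1,000 seeded refits for CI coverage — sizes
chosen so the whole suite completes in about a minute while keeping
binomial noise on the measured rates small. Degenerate inputs are
defined, not errors, wherever the protocol can proceed: empty tight
masks become non-detections, empty peak masks count zero spots,
collinear masks get aspect ratio 0, and a zero-variation boundary gets
infinite circularity. All randomness flows through
`numpy.random.default_rng` from explicit seeds; images are quantised to
integer intensities so regeneration is bit-identical.

## Known limitations

Real exports arrive via TIFF galleries plus a manifest CSV; proprietary
instrument containers are not parsed. The tight-mask algorithm is a
compatible approximation of the instrument software's proprietary
segmentation ("characterise and segment the background"), and the peak
scale is calibrated on the generator, not on that software. Coccospheres
smaller than ~5.7 µm would need a smaller peak footprint than the
default. The field-mode pure gate is deliberately conservative; studies
wanting completeness must review the 5–9 spot band manually.
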