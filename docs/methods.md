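# Methods

## Problem and model

Standing dead trees (snags) at sub-metre resolution appear as compact
brown or grey-white crowns against live canopy. Counting them individually
requires *instance* segmentation: touching crowns in clumped die-offs must
be split, or counts collapse. snagmap uses the deep-watershed idea: instead
of a binary mask, the target is a per-pixel **energy level** in 0..K — the
quantised distance to the nearest crown boundary, with level K at the crown
core and level 1 at the boundary ring. Energy is predicted with **ordinal
classification**: K sigmoid heads give `p_j = P(level ≥ j)`, and level j is
only decodable where level j−1 is present. This guarantees (a) levels keep
their distance meaning, (b) no holes inside predicted crowns, (c) crown
boundaries can be tightened in post-processing by dropping low levels, and
(d) a reversal of the energy gradient marks the border between two touching
crowns, which is exactly where the watershed transform splits them.

### Energy encoding

Per instance, the Euclidean distance transform of the instance's own mask
is computed (so a shared interface between touching crowns counts as
boundary for both), normalised by that instance's maximum distance, and
quantised into K equal bins (`level = ceil(K·d/d_max)`). Per-instance
normalisation (rather than absolute distance) makes both small and large
crowns reach level K, so the marker logic does not depend on crown size;
`energy_normalisation="absolute"` is available for comparison. K is not a
physically forced constant; the default K = 5 keeps each ring ≈ 1 px for
the 2–7 px crown radii that 0.6 m GSD imagery produces. A single-pixel
instance degenerates to level K directly.

Decoding applies cumulative-product enforcement `q_j = Π_{i≤j} p_i` and
`level = max{j : q_j ≥ t}` with threshold t = 0.5 (the symmetric decision
point; config-surfaced). The output is nested by construction.

### Network and training

The network is a small U-shaped encoder–decoder (two 2× poolings, skip
concatenations, batch norm after every convolution, per-level sigmoid
heads), implemented directly in numpy with hand-derived backprop (im2col
convolutions, standard batch-norm gradients, Adam). Two width presets
exist: `small` (8/16/32 channels, ~30k parameters — every result in the
test suite uses this) and `full` (24/48/96). The forward/backward pass is
single-threaded and bit-reproducible for a fixed seed; the gradient is
verified against finite differences in the test suite.

Loss: Focal Tversky, `mean_j (1 − TI_j)^γ` with
`TI = (TP + s)/(TP + α FP + β FN + s)` on soft predictions, per energy
level, smoothing s = 1 (an empty level scores TI = 1, loss 0).
Defaults (α, β, γ) = (0.4, 0.6, 2): β > α weighs false negatives more
heavily than false positives, countering the extreme class imbalance of
sparse small crowns, and γ = 2 focuses training on the poorly-fit levels;
at α = β = 0.5, γ = 1 the loss reduces to soft Dice (asserted in tests).

Augmentation applies, with probability 0.35 each (the 20–50 % range):
a joint affine warp (rotation, shear ≤ 0.2, anisotropic scale 0.9–1.1) to
image and instance labels — energy targets are re-encoded from the warped
labels so ordinal nesting is preserved — and image-only spectral jitter
(global gain 0.85–1.15, per-band gain 0.92–1.08, offset ±0.04).

Data are split 8:1:1 (train/validation/test) by the run seed. After each
epoch the validation patches are fully decoded (enforcement + watershed)
and the **count MAE per patch** recorded; the checkpoint with the minimum
is kept. Selection by count, not loss, matches the quantity the map is
used for. Optimiser defaults: Adam, lr 1e-3 (3e-3 for tiny overfit runs),
batch 8, 15 epochs at the default desk scale of 200 patches of 128×128 px
— sizes chosen so a full run finishes in a few minutes on one CPU core.

Prediction tiles large rasters into overlapping patches (default 256 px,
overlap 32) and blends per-level probabilities with a triangular centre
weight before decoding, suppressing tile-edge artefacts.

### Instance extraction

Watershed markers are the connected components of the top non-empty energy
level within each basin (connected component of the level ≥ 1 mask) —
ordinal nesting makes level cores natural seeds. Flooding runs on −level
with 8-neighbour connectivity ("connectivity 2"), masked to level ≥ 1;
components under `min_pixels = 8` are dropped as speckle (the detection
stage of the emulated survey reports no explicit minimum, so this is an
artifact choice, config-surfaced). Per instance: holes filled, polygon
assembled from pixel footprints in map coordinates, area from pixel count
× pixel area, centroid from moments, ellipse from second-order moments
giving semi-axes a ≥ b, focal distance c = √(a²−b²) and eccentricity
e = c/a. Both semi-axes are floored at half a pixel so degenerate
single-pixel or collinear regions return e well inside [0, 1).

Crown-shape screening: per 500 m cell, the median e over crowns larger
than 50 px (18 m² at 0.6 m GSD — smaller rasterised crowns carry no
reliable shape signal); cells with median e > 0.8 are flagged, and
area-derived products there should be used with caution. No geometric
correction of crown sizes is attempted (it would require the raw imagery's
view-angle metadata).

## Mortality staging

Mean crown RGB is taken after a one-pixel inner buffer (3×3 erosion); if
erosion empties a small crown the un-eroded mask is used (logged). The
mean colour is converted to hexcone HSV (H, S, V ∈ [0, 1]) and scored:

    H_g = 1 − |H − 1/3| / (1/6)          H_r = (1/2 − H)/(1/6) − 2
    X_green = f(C_g, H_g) if H_g ≥ 0     X_brown = f(C_r, H_r) if H_r ≥ 0
    X_grey  = f(C_y, 1 − S)              X_background = f(C_b, 1 − V)

with `f(C, x) = (C^x − 1)/(C − 1)` and C = (5, 5, 1e7, 1e4). The two
hue-based numerators are typeset ambiguously in the source formula block
(`C^{x−1}` vs `C^x − 1`); the grey/background scores unambiguously use
`(C^x − 1)/(C − 1)`, which maps [0, 1] onto [0, 1], so that reading is the
default for all four (a `literal_exponent` flag implements the other).
Conventions for undefined hue/saturation: S = 0 voids both hue scores;
V = 0 (black) additionally voids the grey score so the background score
dominates. Red hues near H = 1 are wrapped (H → H − 1) before H_r, since
warm colours live on both ends of the hue circle; the resulting H_r > 1 is
clamped to score 1. Exact ties resolve grey > brown > green > background —
conservative with respect to claims of *recent* mortality. Crowns whose
argmax is green or background are kept as records but flagged
`unclassified` for QA rather than silently dropped.

The brown-stage percentage per 100 m cell suppresses cells with exactly
one brown tree (set to 0 %, or dropped to nodata with
`drop_single_brown`) — single-tree brown calls are treated as staging
noise. Plot-level validation sums gridded brown counts under survey
polygons ≥ 1 ha and reports the zero-brown (false-negative) fraction.

## Grids and bias correction

All crown→cell assignment is by centroid in half-open, axis-aligned cells
anchored at the raster's top-left corner (grid anchoring is a convention
choice; the origin is configurable). 30 m count grids are always raw —
per-cell analyses (cluster-size profile, isolated-tree share) must not mix
in a smooth correction term. Coarser count grids may add the mean count
error per hectare, `ME = F · mean(Y_obs − Y_pred)` with F the patch→ha
scale factor, scaled to the cell area, so patch-level systematic error
does not accumulate into regional totals; correction applies to cells of
the mapped footprint and the total changes by exactly n_cells × ME ×
cell_ha (asserted). Percent mortality divides by a user-supplied live-tree
baseline (zero baseline → nodata; > 100 % clamped with a warning).
The 3-prong hotspot composite rescales count / brown % / median crown size
per band between that band's own 2nd and 98th percentile over valid cells
of the run's extent, clamps to [0, 1], and maps them to R/G/B; a constant
band is set to 0.5.

## Damage-agent attribution

Survey polygons carry 1–3 agent codes and a survey year; fire perimeters a
year. Overlaps resolve by year precedence: the later survey record wins
(mortality is reported between consecutive surveys); equal years take the
union of agent lists truncated to three in sorted code order (the
truncation commutes with pairwise merging, so the result is independent of
input order); a fire at least as recent as the survey record appends FIRE
(possibly a fourth code — the survey cap does not apply to the fire term),
an older fire changes nothing. The overlay is materialised as a planar
partition of disjoint resolved regions; each crown takes the agents of the
region covering its centroid (a tree has one death and one location — no
area weighting), boundary ties going to the later-year region. Drought
point records enter as fixed-radius buffered survey polygons. A 10-code
demonstration hierarchy (level 4 → 3 → 2 → 1) ships in code; real
taxonomies load from CSV.

## Evaluation protocol

Count metrics per patch/plot: MAE, relative total error
`|Σ err|/|Σ obs|`, and bias `100·Σ(Y_obs − Y_pred)/Σ Y_obs` — **positive
bias = underestimation**, stated on every output. Pixel metrics: per-class
IoU = TP/(TP+FP+FN) and mIoU over background + dead classes; a class
absent from both masks scores IoU 1 by convention (control patches),
excludable by flag. Field comparison: predicted crowns buffered by 6 m
(geo-referencing accuracy of the emulated imagery); points match by
containment (one-to-many by default; an optional Hungarian one-to-one
assignment exists), observed crown polygons by > 50 % coverage, plots by
predicted centroids inside the 6 m-buffered plot polygon, census plots
filtered to DBH ≥ 40 cm when DBH is recorded. The tree-level "bias" is
reported both as matched % and 100 − matched %, since both readings are
in circulation.

## Synthetic scenes: what they emulate, and what they do not

Scenes emulate the imaging conditions the pipeline targets: 0.6 m GSD,
8-bit 4-band tiles; live-canopy background with smooth brightness texture;
dead crowns as filled ellipses drawn from brown/grey HSV palettes with
per-crown jitter; NIR low for dead crowns relative to live canopy
(chlorophyll loss); 40 % of crowns in clumps (later crown rendered on top,
both kept in truth — clump splitting is the point); a scene-wide affine
shear standing in for off-nadir distortion; additive per-band noise
(σ = 3 DN). The default density, ~9 crowns per 128 px patch, matches the
label density of the emulated training campaign (~38 dead trees per
256 px patch). The brown/grey palettes are constructed to classify 100 %
correctly under the staging formulas (hue < 1/6 with moderate saturation
vs. cyan-tinged low saturation), which is asserted at generator-build
time — staging tests on synthetic scenes therefore verify the *plumbing*,
not the discriminative power of the constants on real imagery.

Not emulated: radiative transfer, shadows, terrain, species mixtures,
understory and severely decayed snags, inter-annual registration error.
Passing tests show the algorithmic chain is correct and self-consistent at
realistic geometry and density; they do not certify accuracy values on
real imagery.

## Numerical choices and degenerate inputs

- float32 network arithmetic; losses and sigmoids accumulated in float64.
- Deterministic for fixed seeds throughout (single master seed per run;
  every artifact embeds the config hash).
- Tiling shifts the trailing patch inward instead of padding; rasters
  smaller than one patch are zero-padded (logged).
- 3-band rasters get a synthesised zero NIR band with a warning; a missing
  CRS is a hard error; CRS agreement is verified, never reprojected.
- Empty erosion → un-eroded fallback; empty cells → nodata (NaN); zero
  observed totals → metrics reported as NaN rather than raised.

## Known limitations

- The numpy network is deliberately small; it demonstrates and tests the
  method but is not meant to transfer to real NAIP campaigns without a
  GPU-scale re-implementation and real labels.
- GeoJSON is the only vector format (GeoPackage/Shapefile are not read);
  CRS handling is identifier-only.
- The staging constants are taken as given, not re-fitted; their reported
  accuracy on real imagery is not reproduced here.
- Attribution inherits the coarseness of survey polygons; compound-event
  attribution beyond the year-precedence rules is out of scope.
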