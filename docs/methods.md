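# Methods

This note documents the models, algorithms and numerical choices behind
`iftomo`: what the synthetic phantom emulates, how each pipeline stage
works, which parameters matter, and what the phantom-based tests do and
do not demonstrate about real data.

## Coordinate and intensity conventions

Pixels are 0-based with the origin at the top-left pixel *center*;
x = column, y = row; angles are in degrees, counter-clockwise, and all
rotations are taken about the image center. Volumes are stored
`(channel, z, y, x)` with anisotropic voxels: x and y carry the pixel
pitch (default 0.44 µm, a 20X widefield objective), z carries the
physical section thickness (default 2 µm). The z extent of a stack is
therefore always `n_sections × thickness`; no resampling to isotropic
voxels is performed inside the pipeline, because the axial resolution
*is* the section thickness and interpolating along z would manufacture
information. Quantization to unsigned integers is round-half-up followed
by clipping, applied exactly once per image (after any resampling).

## The phantom

The generator (`iftomo.phantom`) emulates the acquisition chain:

- **Tissue.** `n_cells` spherical nuclei with radii uniform in
  `nucleus_radius_range` inside a box `tissue_extent` (µm). Two
  placement regimes: `enforce_separation=True` keeps nuclei apart so
  that each remains a distinct 3-D object after sectioning (required
  for exact counting), using an either/or rule — in-plane clearance of
  `min_separation` between circles, or a z-gap wide enough that at
  least one full empty slab lies between two in-plane-overlapping
  nuclei (slab projection smears a nucleus across every slab it
  touches, and 26-connectivity bridges adjacent slabs).
  `enforce_separation=False` produces dense tissue with touching
  nuclei, appropriate for registration benchmarks.
- **Label dilution.** Each cell draws a division count uniformly from
  `0..divisions_max`; its true GFP intensity is
  `initial_intensity × 0.5^divisions` (real-valued; 8-bit quantization
  happens at rasterization). The DAPI channel carries every nucleus at
  full intensity.
- **Sectioning.** `ceil(extent_z / thickness)` slabs. Each section is
  the maximum-intensity projection of the analytic nucleus profiles
  through its slab: with 2 µm sections every nucleus lies within the
  focal plane, so the in-plane footprint is governed by the largest
  in-plane radius the sphere attains inside the slab. Nuclei are solid
  spheres with a soft linear 1-pixel edge falloff — the simplest shape
  segmentation can recover exactly.
- **Block geometry.** `z_overhang` lets the tissue continue past the
  sectioned range, as it does in a real block, so the first and last
  slabs are as densely populated as the middle; `field_margin` images
  empty slide around the tissue so a misplaced section never pushes
  content out of frame; `stratify_z` spreads nuclei evenly along z
  (real tissue is more even than a Poisson draw because cells exclude
  volume), keeping every slab populated. With `z_overhang` some cell
  centroids lie outside the sectioned range; the truth-table oracle
  excludes cells that no slab intersects.
- **Misplacement and noise.** Every section after the first receives a
  rigid misplacement drawn uniformly within `misalignment_range`
  (|tx|, |ty| px; |θ|°); section 0 is the unperturbed reference.
  Additive Gaussian noise (`noise_sd`) and a constant background are
  applied after warping, then the image is quantized. Optics (PSF,
  depth blur), bleaching, chromatic shift, and section folds are not
  simulated.
- **Tiling.** A section can be cut into a rows × cols mosaic. The tile
  size is the smallest integer `w` with
  `c·w − (c−1)·overlap·w ≥ extent`; nominal origins stride by
  `w × (1 − overlap)` with the last tile clamped to the image edge.
  With `tile_jitter_px`, true origins deviate from nominal by a bounded
  uniform integer perturbation (the first tile is the anchor), and the
  true origins are recorded in the ground truth.

Everything is driven by one `numpy` generator seeded from `seed`: the
same configuration and seed reproduce the dataset bit for bit.

## Stitching

Translation-only (tiles come from one motorized scan of one section).
Tiles are placed row-major; each tile is refined against its left and
top neighbors by maximizing the normalized cross-correlation (NCC) of
the overlap strip over integer offsets within `search_radius` of the
nominal offset, then interpolated to sub-pixel with a 1-D quadratic
through the peak along each axis. Conflicting neighbor estimates are
resolved by a confidence-weighted average (confidence = peak NCC), and
refined origins are clamped to within the search radius of nominal. A
vanishing quadratic distance penalty (10⁻⁶ per px²) breaks correlation
ties toward the nominal stage position, which matters when a seam strip
is nearly flat. A strip with zero variance carries no alignment
information: the nominal offset is kept with confidence 0 and a
warning. Blending widens to float and re-quantizes once at the end;
`feather` weights each tile by an integer distance-to-edge ramp
(weights sum to unity after normalization, so identical overlapping
content reproduces exactly, bit for bit), `overwrite` lets the last
tile win. A known limitation: if the true seam content is entirely
featureless *and* the stage position is wrong, no correlation evidence
exists and the nominal position is the best available answer.

## Registration

Rigid only — sections are physical slices of one block, and no
deformable correction is attempted. Similarity is computed on the DAPI
channel after light Gaussian smoothing (σ = 1 px). Two cooperating
estimators:

1. **Global landmark search.** Nucleus centers are detected as local
   maxima of the euclidean distance transform of the foreground mask
   (the incircle center of a disk is independent of its radius), with
   sub-pixel refinement by the weighted centroid of the near-peak
   plateau. The key property: a nucleus projects to the *same* in-plane
   center in every section it intersects, even though its apparent
   radius changes from slab to slab — so centers are stable landmarks
   across consecutive sections. For every candidate correspondence
   (one landmark from each image) and every rotation candidate within
   the bound (1° steps), the implied translation is scored by how many
   landmarks find a one-to-one partner within 2 px; the best hypotheses
   are polished by a closed-form rigid Procrustes fit on their inliers
   and verified by NCC of the warped pair. This resolves the
   rotation/translation trade-off that a correlation ridge over large,
   radially symmetric blobs leaves nearly flat.
2. **Correlation sweep fallback.** Rotation candidates at 0.5° steps
   over ±`max_rotation`; per candidate the translation is solved by
   phase correlation; the best candidate's angle is refined by bounded
   scalar minimization (0.01° tolerance) with sub-pixel phase
   correlation (upsampling factor 20), followed by an ICP-style
   landmark polish. The final score is the NCC over the validly
   overlapping region; candidates whose warp throws more than half the
   frame out of bounds are rejected, since tiny overlaps yield spurious
   correlations.

The landmark solution wins unless the correlation evidence against it
is decisive (NCC more than 0.05 below the sweep's best). A pair whose
final score falls below the confidence floor (default 0.1) gets the
identity transform, score 0, and is recorded as flagged — never
silently dropped. Stack alignment chains consecutive pairs
(`absolute[i] = absolute[i−1] ∘ pairwise[i]`) from a reference section
(default the first) and resamples every channel of every section
exactly once with its absolute transform (bilinear, zero fill).
Re-probe fusion registers a re-stained round of the same physical
section to the first round on DAPI and appends its non-DAPI channels
(duplicate names suffixed `_r2`); a sub-floor registration raises
rather than silently misaligning. Drift: chaining accumulates per-pair
error roughly additively; with per-pair errors below 0.1 px the
end-of-stack error over 50 sections stays well under a pixel. An
optional running-mean reference was considered and left out — at the
measured per-pair accuracy the added complexity buys nothing.

## Quantification

Segmentation binarizes a channel (fixed threshold, or Otsu on the
channel histogram for the automatic strategy), labels 3-D connected
components with 26-connectivity, removes components below
`min_volume_voxels`, and tabulates per-object voxel count, centroid
(µm) and mean intensity in every channel. Raising the threshold never
increases foreground voxels (asserted); the object *count* is not
monotone in the threshold because bridges can split. The default
minimum volume for pipeline runs is the voxel volume of a sphere at the
smallest configured nucleus radius; note that a high fixed threshold
segments only the bright core of each nucleus (the soft 1-px rim falls
below it), so oracle-equivalence runs pass an explicitly smaller
minimum volume.

An object is an LRC when its mean intensity in the label channel
reaches `lrc_floor` (default 1, i.e. any signal above a zero
background; the positivity criterion on real data is a user decision
and the parameter is exposed). LRCs are graded by *mean* (not maximum)
intensity — stable under noise — into half-open bins on the 8-bit
range, `[0,100) / [100,200) / [200,255]`: "200 and above" places 200 in
the high bin, and the same convention is applied downward, so each of
the 256 grey levels maps to exactly one bin. Percentages are reported
to the nearest integer (raw fractions are also emitted), and
conservation (bins sum to the LRC total, LRC total ≤ nuclei) is
asserted in every report. The averaged count over three thresholds
(high/medium/low) takes the three values explicitly and returns their
arithmetic mean; equal thresholds are allowed and reduce to a single
count, decreasing ones are rejected. Touching nuclei are not split
(no watershed in this version): they count as one object, which is why
exact-counting phantoms enforce separation.

### Why the exact-counting configuration works

In a noise-free phantom the nucleus core rasterizes to the quantized
true intensity, while the 1-px rim is darker. Segmenting DAPI at a
fixed threshold of 250 keeps only near-plateau voxels; for those voxels
the GFP value rounds to within one grey level of the quantized core
value, so the object's mean GFP lands in the same bin as the truth
value for every dilution level (the possible values 255, 128, 64, …, 1
all sit far from the bin edges at 100, 200 and from the LRC floor at
1). The truth-table oracle applies the same 8-bit quantization the
rasterizer applies before binning — binning the unquantized value
0.5⁸ × 255 ≈ 0.996 would disagree with *any* measurement on 8-bit data,
where that cell reads exactly 1.

## Benchmark study conditions

The packaged benchmarks (`iftomo.benchmark`) fix the problem sizes used
by the test suite and the acceptance script:

- **Registration:** 50 sections (100 µm at 2 µm), 80 nuclei of
  4.5–6 µm radius in a 72 µm-wide core, 10 µm field margin, 6 µm block
  overhang, stratified z, misplacements up to ±15 px / ±5°, noise SD
  12.75 (5% of the 8-bit range); search bound ±11° (two consecutive ±5°
  draws can differ by 10°). Measured: mean pairwise recovery error
  ~0.06 px / ~0.04°, end-of-stack error ~0.3 px.
- **Stitching:** a dense 80 µm section (120 nuclei) tiled 2×2 and 8×8
  at 10% overlap, reassembled bit-exactly at true origins under both
  blends; a 2×2 tiling with ±3 px origin jitter refined to ≲0.1 px.
- **Counting:** 200 separated nuclei (2.5–4 µm) with 0–8 divisions in a
  160 × 160 × 60 µm block, noise-free; measured report equals the
  truth-table computation exactly.

These sizes keep the full suite under a minute of compute while leaving
each check far from its tolerance.

## What the phantom does and does not show

Passing phantoms demonstrates the computational chain: geometry
bookkeeping, transform algebra and resampling, correlation and landmark
estimation, connected-component counting, binning arithmetic and
reproducibility. The phantom does not model out-of-focus light, uneven
illumination, staining variability between rounds, section compression
or folds, nuclear texture, or segmentation of genuinely touching
nuclei; results on real slides will degrade with those factors, and the
flagged-pair mechanism plus the per-object CSV are the intended entry
points for manual review.
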