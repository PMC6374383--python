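# iftomo — immunofluorescence tomography

`iftomo` reconstructs high-resolution 3-D volumes from 2-D images of
immuno-stained plastic serial sections and quantifies cell
sub-populations in the reconstructed volume. It is written for
microscopists and image analysts who cut tissue embedded in
butyl-methyl methacrylate (BMMA) into 2 µm serial sections, stain and
image every section in 2-D (optionally as a mosaic of overlapping
tiles), and want a reproducible, scriptable path from those images to
counted, intensity-graded cells in 3-D.

The pipeline has five stages, each usable on its own:

1. **simulate** — generate a synthetic serial-section *phantom* with a
   complete ground truth (cell centroids, radii, division counts, true
   intensities, per-section misplacements, true tile origins), so every
   downstream stage can be validated without real slides;
2. **stitch** — assemble each section's mosaic tiles (10% nominal
   overlap) into one image, refining tile positions by normalized
   cross-correlation of the overlap strips with sub-pixel peak
   interpolation;
3. **align** — rigidly register the ordered sections on the DAPI
   channel: a global nucleus-landmark correspondence search backed by a
   rotation-swept phase-correlation fallback, chained into absolute
   transforms relative to a reference section;
4. **assemble** — stack the aligned sections into an anisotropic-voxel
   volume (x, y = pixel pitch, default 0.44 µm; z = section thickness,
   default 2 µm), so a stack of *n* sections spans *n* × 2 µm of tissue;
5. **quantify** — segment nuclei by thresholding + 3-D connected
   components (26-connectivity), grade label retention on the 8-bit
   range into low [0, 100), mid [100, 200) and high [200, 255] bins,
   and report counts and percentages.

## The science in brief

In an H2B-GFP pulse-chase system, nuclei express a GFP-tagged histone
during the pulse; during the chase each cell division dilutes the label
by half, so a cell that has divided *k* times retains

    I(k) = I0 · 0.5^k

of the initial nuclear fluorescence `I0`. Slow-cycling (quiescent) cells
remain bright — label-retaining cells (LRCs) — and the retained
intensity indexes how many times a cell has divided. Sectioning at 2 µm
puts every nucleus in the focal plane, so per-nucleus intensities are
quantitative, and binning mean nuclear GFP into low/mid/high grades
separates LRC sub-populations in 3-D. Because DAPI is present in every
staining round, the same nuclear pattern also registers consecutive
sections to each other and re-probed rounds of one section to each
other, which is how more than four fluorescent channels are accumulated
on a single physical section.

## Worked example

Run the full pipeline on the default phantom (60 nuclei in a
60 × 60 × 40 µm block, 20 sections at 2 µm, 0.44 µm pixels):

```sh
iftomo run --out demo --seed 7
```

prints

```
60 nuclei, 53 LRCs (low/mid/high = (38, 6, 9) = (72, 11, 17)%)
artifacts in demo (run.json written)
```

Reading the numbers: segmentation of the DAPI channel (automatic Otsu
threshold) found 60 nuclei in the reconstructed volume; 53 of them carry
GFP signal (mean intensity ≥ 1 on the 8-bit scale) and are LRCs. Binning
each LRC's mean GFP intensity grades 38 as weak label-retainers
(intensity below 100 — cells that divided often), 6 as intermediate and
9 as strong (200 and above — the most quiescent cells); the percentages
are of the LRC total. `demo/` contains the generated sections with
their ground truth (`truth.json`), the recovered per-section transforms
(`transforms.json`), the volume (one multi-page TIFF per channel plus a
`volume.json` geometry sidecar), a per-object table (`objects.csv`), the
count report (`report.json`) and the resolved configuration with seed
and timings (`run.json`) from which the run can be repeated exactly.

Each stage also works standalone, e.g.

```sh
iftomo simulate --out sim --seed 3 --n-cells 40 --extent 60 60 30
iftomo align --manifest sim/manifest.json --channel DAPI --out aligned
iftomo assemble --aligned aligned --out vol
iftomo quantify --vol vol --lrc-channel GFP --bins 0,100,200,255 --out report
iftomo stitch --tiles tiles/ --grid 8x8 --overlap 0.10 --out section.tif
```

and the same functionality is importable (`iftomo.generate_phantom`,
`iftomo.align_stack`, `iftomo.assemble`, `iftomo.segment_nuclei`, ...).

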