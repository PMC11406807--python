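# chopct

Semi-automated 3D segmentation and morphometric analysis of the embryonic
hindbrain choroid plexus (HbChP) from contrast-enhanced micro-CT stacks,
plus a synthetic phantom generator so the whole pipeline can be built,
tested and benchmarked offline without scan data.

## What it does

- **phantom** — synthetic embryo-head volumes: a dark CSF-filled ventricle
  cavity in mid-intensity tissue, a bright branched plexus inside it, a
  decoy cavity joined by a thin dark channel, Gaussian noise at a
  controllable contrast-to-noise ratio, plus ground-truth masks, a
  reference-ventricle mask and landmark sets.
- **io_formats** — per-slice TIFF stacks, 8-bit 0/255 mask TIFFs, STL
  surface export (marching cubes), Slicer Markups `.fcsv` landmarks, CSV
  morphometry reports.
- **quality** — contrast-to-noise ratio `|mean_fg - mean_bg| / sigma_bg`
  (raw ratio plus both dB conventions).
- **ventricle** — median-filter/crop preprocessing, low-intensity (Otsu)
  thresholding, morphological separation into connected components, rigid
  ICP registration of each candidate against a reference ventricle mask
  with Hausdorff-distance selection, Chan–Vese refinement on the
  complemented image.
- **plexus** — primary mask via morphological closing of the lumen and
  high-intensity filtering of the closing gap; full automatic E13.5
  segmentation (local range analysis, intensity filtering, active
  contour); primary-mask export and manual-branch merging for E15.5/E17.5.
- **morphometry** — volume, Crofton-formula surface area (3- and
  13-direction modes), principal-axis outgrowth angle, ventricle
  proportion, rostrocaudal plane split, and automated analogues of the
  transverse-plane branch length/angle measurements.
- **gpa** — Generalized Procrustes Analysis with per-sample Procrustes
  distances, fixed-reference mode and landmark-subset mode.

Array convention throughout: `(z, y, x)` indexing, `z` the rostrocaudal
stack axis, physical coordinate = index × `voxel_size_mm` (isotropic).

## CLI

```sh
chopct phantom --out out/phantom --seed 1          # synthetic data + truths
chopct cnr --image IMG_DIR --fg FG_DIR --bg BG_DIR
chopct ventricle --image IMG_DIR --reference REF --out out/vent
chopct segment --stage E13.5 --image IMG_DIR --reference REF --out out/seg
chopct segment --stage E15.5 --image IMG_DIR --reference REF \
       --manual-branches BRANCH_DIR --out out/seg
chopct morpho --plexus MASK_DIR --ventricle MASK_DIR --out report.csv
chopct gpa --landmarks DIR_OF_FCSV [--reference mean.fcsv] \
       [--subset 5,6,7,8,10,11] --out distances.csv
chopct pipeline --phantom --stage E13.5 --seed 7 --out out/run
```

Every run writes a `provenance.json` (config hash, version, timings); all
parameters live in one JSON config (`RunConfig`) with strict unknown-key
rejection.

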