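# quapos

Quantification of photoreceptor outer segments (POS) on microscopy images,
across two scales:

* **TEM track** (`quapos.tem`) — nematic orientation analysis of membrane
  stacks on 2D transmission electron micrographs. Per-pixel directors are
  derived from the image intensity gradient (an optimized 5×5 derivative
  operator with sub-1e-5-degree orientation bias), summarized by Q-tensors
  into *local* coherency (25×25 sliding boxes) and *global* coherency per
  region of interest, plus per-replicate alignment of ROI directions.
* **LM track** (`quapos.lm`) — segmentation of labelled cone outer segments
  on 3D fluorescence stacks with a portable 100-tree / depth-2 random-forest
  pixel classifier over a small convolutional feature bank, followed by
  isotropic resampling (0.323 µm), 26-connected morphometry (volume,
  bounding-box height, Feret diameter, sphericity, intensity statistics),
  and a pooled 5–95 % volume-percentile filter.

Supporting modules: `quapos.rois` (ImageJ `.roi`/`.zip` reader–writer and
rasterization), `quapos.stats` (replicate-hierarchy averaging, Pearson
matrix, one-way ANOVA + Tukey HSD, Welch's t-test), `quapos.synth`
(synthetic membrane textures and 3D ellipsoid phantoms with ground truth).

## Command line

```sh
# synthetic fixtures
quapos synth membrane --seed 1 --out demo/mem
quapos synth phantom  --seed 1 --out demo/ph

# TEM track: per-ROI coherency summary, then per-replicate alignment
quapos tem analyze --image demo/mem/membrane.tif --rois demo/mem/membrane_rois.zip --out demo/tem
quapos tem alignment --summary demo/tem/membrane_coherency.csv --out demo/alignment.csv

# LM track
quapos lm preprocess --image raw.tif --out pre.tif
quapos lm train --image pre.tif --annotation ann.csv --seed 0 --out model.quapos.json
quapos lm predict --model model.quapos.json --image pre.tif --out mask.tif
quapos lm validate --pred mask.tif --ref ref.tif --out scores.csv
quapos lm quantify --model model.quapos.json --image pre.tif --out quant/
```

Annotation CSVs carry columns `z,y,x,label` (label 0 = background,
1 = signal). Trained models serialize to a self-contained JSON document
(trees, feature bank, seed, format version) and predict without
scikit-learn at load time.

## Conventions

* Images are arrays indexed `[row (y), column (x)]`, y increasing downward;
  stacks are `[z, y, x]` with voxel size given as `(z, y, x)` in µm.
* Directors are angles in `[0°, 180°)` measured from the +x axis; a gradient
  `(gx, gy)` maps to the director of `(gy, −gx)`.
* Coherency is the weight-normalized scalar nematic order parameter,
  `2·√(Qxx² + Qxy²) / Σm ∈ [0, 1]`.
* Default TEM pixel size is 1/287.5 µm; the local coherency box radius
  defaults to 12 (25×25 boxes); validity requires full kernel support
  inside the ROI (erosion by 2 px for global, 14 px for local queries).
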