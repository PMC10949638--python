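# trichoseg

Quantify leaf hairiness from surface microscopy images. The toolkit covers
the full pipeline:

- **`trichoseg.annot`** — spline trichome annotations (ordered control
  points at a reference resolution), sparse binary masks stored as
  foreground indices, dataset JSON I/O, and deterministic
  train/val/test splitting (floor/floor/remainder rounding).
- **`trichoseg.synthleaf`** — a procedural generator of leaf-like images
  (textured background, bright midvein band, thin bright curvilinear hairs)
  with exact ground-truth splines, so every downstream stage is testable
  without any dataset download.
- **`trichoseg.augment`** — paired image/annotation augmentation with the
  compact recipe names `RS<size>` (resize), `RC<size>` (random crop) and
  `RF` (random flips). Geometry is applied to spline control points and the
  mask is drawn once, at the final resolution — masks are never resampled,
  which is what keeps thin strokes from breaking apart.
- **`trichoseg.segnet`** — modular binary segmentation: encoders (VGG19-bn,
  ResNet18/50, SE-ResNet50, RegNetX-064, EfficientNet-B5, plus a `tiny`
  CPU backbone) × decoders (UNet, UNet++, DeepLabv3, LinkNet, MANet), four
  losses (BCE, Dice, Jaccard, Focal), an Adam training loop with validation
  IoU checkpointing, and sparse mask prediction. Runs on a built-in numpy
  autodiff engine (`trichoseg.nn`) — no GPU frameworks required, fully
  deterministic given a seed.
- **`trichoseg.quantify`** — IoU/F1 evaluation, the scaled trichome-density
  score `1000 * foreground / total` pixels, batch scoring, factor-wise
  aggregation (mean/median, sd, 95% t-CI), genotype ranking and Spearman
  rank correlation.
- **`trichoseg.experiment`** — the encoder×decoder×recipe×loss grid study
  with mean ± range repeat reporting, content-hash resumability and
  deterministic cell seeding.
- **`trichoseg.cli`** — the `trichoseg` command.

## CLI walkthrough

```sh
# 1. generate a synthetic panel (images + annotations.json + truth masks)
trichoseg generate --config panel.yaml --seed 1 --out data/

# 2. train a tiny model
trichoseg train --data data/ --recipe RS256+RF --epochs 10 --out model/

# 3. evaluate, score, rank
trichoseg eval  --data data/ --checkpoint model/checkpoint.npz --out eval/
trichoseg score --data data/ --checkpoint model/checkpoint.npz --out scores/
trichoseg rank  --scores scores/scores.csv --out ranking/

# architecture study
trichoseg grid --config grid.yaml --data data/ --out grid/
```

A minimal `panel.yaml`:

```yaml
base: {image_size: [256, 256], hair_length_px: [50, 15]}
images_per_genotype: 4
genotypes:
  - {name: sparse, nominal_class: "1", hair_count: [5, 1]}
  - {name: hairy,  nominal_class: "4", hair_count: [60, 1]}
```

Every command writes `provenance.json` (config + version + seeds) next to
its outputs.

## Notes

- Pixel convention: 0-based `(row, col)`, pixel centers at integer
  coordinates; rasterization rounds to nearest.
- Splines are interpolated with centripetal Catmull-Rom through the
  annotator-placed control points and drawn with a disc brush
  (`stroke_width` diameter, default 2 px).
- `pretrained=True` is rejected: this implementation is fully offline and
  trains from scratch.
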