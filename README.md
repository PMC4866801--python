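# peagrade

Classification of field pea seed samples into broad market grades, and
screening of defective samples, from per-seed image stacks: six
colour-intensity images (violet 405, blue 470, green 530, orange 590,
red 660 and NIR 850 nm) plus a co-registered laser surface-height image.

Because no real imagery is bundled, the package ships a synthetic seed
renderer that emulates the stack format and the statistical structure the
analysis assumes (grade-specific reflectance, size and dome height;
disease staining, exposed cotyledon, shrivelling and insect damage), so
the whole pipeline is testable end to end.

## Pipeline

1. **synth** — render seeds as elliptical height domes with per-channel
   intensity proportional to height; generate full calibration/validation
   datasets (default: 175 + 142 samples across eight market grades, 39
   defective in each split, 30 seeds per sample).
2. **preprocess** — per seed, build mask `m1` (segmentation: height
   floor, 3×3 closing, hole fill, largest 4-connected component) and
   `m2` = `m1` ∧ (height > 20 units), which trims shadow-corrupted
   boundary pixels.
3. **features** — 13 features per seed: six height-corrected colour
   factors (median of intensity/height over `m2`), median seed height,
   equivalent diameter, area, plumpness, perimeter, volume, circularity.
   Per-sample values are seed-wise medians; vectors are standardised with
   calibration-set means/SDs.
4. **discriminant** — per-feature one-way F screen + SVD rank check;
   from-scratch LDA (class means, pooled within-class covariance);
   nearest-Mahalanobis classification with equal priors; greedy forward
   feature selection; Mahalanobis diagnostics by defect status.
5. **pipeline** — the three models:
   * **model1**: blue/green/orange/red factors, trained on non-defective
     calibration samples, 7 grades (Yellow Forage excluded);
   * **model2**: model1 features + violet factor, equivalent diameter,
     circularity, plumpness; full calibration set, 8 grades;
   * **defect**: same 8 features, defective vs non-defective.

## CLI

```sh
peagrade generate --design design.toml --out data/ --seed 1   # TIFF stacks + manifest.tsv
peagrade extract  --manifest data/manifest.tsv --out features.tsv
peagrade run      --features features.tsv --models model1,model2,defect --out report/
peagrade all      --seed 1 --out report/                      # full chain in memory
```

Design TOML (all keys optional; omitted cells use the built-in design):

```toml
seeds_per_sample = 30
[cells."White"]
calibration = [50, 4]   # total, defective
validation = [45, 4]
```

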