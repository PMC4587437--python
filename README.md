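# lungcad

Automated computer-aided detection (CAD) for chest CT: segment the lungs
from a single axial slice, characterise each lung's parenchymal texture
with multiscale AM-FM (amplitude-modulation / frequency-modulation)
features, and classify each lung as normal or cancerous.

The package is aimed at medical-image-analysis researchers who want a
tested, fully reproducible reference implementation of this pipeline. It
ships with an HU-calibrated synthetic phantom generator, so every stage —
and the pipeline end-to-end — runs and is validated without any clinical
dataset.

## Method

The pipeline has five stages, each exposed as library functions and as a
CLI subcommand:

1. **Preprocessing** — adaptive Wiener filtering with a 3×3 window:
   `F = μ + max(σ² − v², 0)/σ² · (I − μ)`, where `μ, σ²` are the local
   window mean and variance and `v²` the noise variance (estimated as the
   mean local variance by default).
2. **Lung segmentation** — the HU histogram of a chest slice shows a
   background spike near −3024 HU, a lung-parenchyma peak (−910…−500 HU),
   and fat/muscle peaks above −500 HU. The threshold is the midpoint
   `T = (I_FM − I_L)/2 + I_L` between the lung peak `I_L` and the mean
   fat/muscle peak `I_FM`. Binarising at `T`, keeping the largest
   component (thorax), filling its holes and subtracting recovers the lung
   cavities, which are then split into left and right rectangular ROIs.
3. **AM-FM feature extraction** — each ROI is modelled as
   `I(k) = Σₙ aₙ(k) cos(φₙ(k))`. The analytic image
   `I_AS = I + j·H₂D{I}` is passed through a four-scale, 25-filter bank
   (one low-pass disc plus H/M/L/VL annuli whose bandwidths halve per
   scale, six 30° wedges each). Per channel, IA `= |I_AS|`,
   IP `= arg(I_AS)`, and IF `= ∇φ` via variable-spacing phase differences.
   Dominant component analysis (per-pixel max-IA channel) over 11 scale
   combinations, followed by 32-bin unit-mass histograms of IA, |IF|, and
   IP, yields a 11 × 96 = 1056-value feature row per lung.
4. **Feature reduction** — partial least squares regression `y = Xβ + ε`
   on the 1056 columns; the factor count is the smallest explaining ≥ 90%
   of the response variance.
5. **Classification** — KNN, linear-kernel SVM, Gaussian naive Bayes, and
   a linear discriminant on the factor scores, evaluated with leave-M-out
   cross-validation and sensitivity / specificity / accuracy (in %)
   computed from the confusion counts.

## Worked example

```python
import lungcad as lc

# 20 phantoms per class -> 40 lung ROIs (20 normal, 20 with a nodule);
# full pipeline incl. leave-M-out CV at the 60/40 train/test split
report, features = lc.demo_synthetic(20, seed=7)
print(features.values.shape)
for kind, s in report.per_classifier.items():
    print(f"{kind:12s} acc {s.accuracy_mean:5.1f}±{s.accuracy_sd:4.1f}  "
          f"sens {s.sensitivity_mean:5.1f}  spec {s.specificity_mean:5.1f}")
```

prints

```
(40, 1056)
knn          acc  94.9± 6.7  sens  93.8  spec  96.0
svm          acc  96.0± 5.8  sens  94.5  spec  97.5
naive_bayes  acc  91.9± 7.8  sens  95.5  spec  88.2
linear       acc  97.8± 4.1  sens  99.0  spec  96.5
```

Each row is one classifier's holdout performance, mean ± sd over 50
stratified random holdouts of 16 of the 40 lung ROIs: accuracy is the
fraction of held-out lungs labelled correctly, sensitivity the fraction of
cancer lungs detected, specificity the fraction of normal lungs cleared.
On these phantoms the nodule plus its roughened surround make the classes
well separable and the linear discriminant performs best.

The same run from a shell:

```sh
lungcad demo --n-per-class 20 --seed 7
```

Other subcommands (`lungcad synth|segment|amfm|features|select|evaluate|run`)
expose the individual stages on directories of DICOM slices or the
PNG+JSON phantom fixtures.

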