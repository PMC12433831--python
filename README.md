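# xirplesion

Semi-automatic detection, quantification and group statistics of
**xirp 1/2-positive sarcomeric lesions** in immunofluorescence images of
skeletal-muscle cross-sections.

Sarcomeric lesions — focal Z-disc disruptions that enrich the xin
actin-binding repeat-containing proteins 1 and 2 (xirp 1/2) — appear as
bright punctate-to-patchy spots over the autofluorescent fiber mosaic of a
stained soleus cross-section. Counting and measuring them by hand is
impractical at whole-section scale, so this package implements the
workflow used in desminopathy mouse studies: a trainable pixel classifier,
calibrated connected-component morphometry inside a manually drawn region
of interest (ROI), a normality/variance-routed statistical decision tree
for six-group (genotype × exercise) cohorts, and interobserver-concordance
analysis. A synthetic-tissue generator with exact ground truth makes every
stage testable without microscope data.

## Method at a glance

- **Pixel classification.** Each pixel of a single-channel image (pixel
  size 0.13 μm/px by default) is described by multiscale features — for
  each scale σ ∈ {0.5, 1, 2, 4, 8} px: Gaussian-smoothed intensity,
  gradient magnitude, Laplacian of Gaussian, and both structure-tensor
  eigenvalues — and labeled lesion/not-lesion by a small neural network
  (one hidden layer of 32 logistic units) trained on sparse polygon
  annotations in two classes (*lesion*, *ignore*). One checkpoint is saved
  per training image; the deployed iteration maximizes pixel-level F1 on
  validation sections, i.e. the best compromise between sensitivity and
  false positives.
- **Morphometry.** Connected components (8-neighbor) of the classified
  raster, clipped to the ROI, with area *A* = pixel count × (0.13 μm)².
  Detections require *A* ≥ 0.01 μm²; **macrolesions** are the subset with
  *A* > 10 μm². Seven readouts per section: ROI area (μm²), lesion count,
  mean lesion size (μm²), macrolesion count, lesion density (/mm²),
  macrolesion fraction (%), macrolesion density (/mm²).
- **Statistics.** Per group: Anderson–Darling normality; across groups:
  Bartlett + Brown–Forsythe variance tests. All normal & equal spread →
  one-way ANOVA + Tukey; normal & unequal spread → Welch/Brown–Forsythe
  ANOVA + Dunnett T3; any non-normal → Kruskal–Wallis + Holm-corrected
  Mann–Whitney. Two-sample contrasts route to Student t / Welch t /
  Mann–Whitney analogously. α = 0.05, summaries as mean ± SEM.
- **Simulation.** Homogeneous spatial Poisson lesion placement inside a
  soleus-like ROI, two-component lognormal size law spanning the 10 μm²
  micro/macro boundary, Voronoi fiber-mosaic background, PSF blur,
  shot/read noise; cohort presets parameterized by the published group
  means of the R349P desmin knock-in treadmill study.

## Worked example

Train on four annotated synthetic sections, select the best checkpoint and
quantify a held-out section (see `tests/conftest.py` for the same flow):

```python
import numpy as np
from xirplesion import *
from xirplesion.synthmuscle import (
    classifier_benchmark_spec, dot_annotations_from_ground_truth,
    generate_tissue_image,
)

stacks, labels = [], []
for s in (100, 101, 102, 103):
    img, gt, roi = generate_tissue_image(classifier_benchmark_spec(seed=s))
    ann = dot_annotations_from_ground_truth(gt, seed=s + 1000)
    labels.append(rasterize_annotations(ann, img))
    stacks.append(compute_feature_stack(img))
clf = train_classifier(stacks, labels, seed=42)

val_stacks, val_truth = [], []
for s in (300, 301):
    img, gt, _ = generate_tissue_image(classifier_benchmark_spec(seed=s))
    val_stacks.append(compute_feature_stack(img))
    val_truth.append(gt.lesion_mask.astype(np.uint8))
clf = select_classifier(clf, val_stacks, val_truth)

spec = TissueSpec(field_size_px=(1024, 1024), lesion_density_per_mm2=2000.0, seed=7)
img, gt, roi = generate_tissue_image(spec)
mask, roi_area_um2 = build_roi_mask(roi, img)
pred = classify_pixels(clf, compute_feature_stack(img))
lesions = extract_lesions(pred, mask, img.pixel_size_um, QuantConfig())
r = quantify_sample(lesions, roi_area_um2, sample_id="demo")
print(f"lesions: {r.lesion_count} (ground truth {len(gt.areas_um2)})")
print(f"lesion density: {r.lesion_density_per_mm2:.1f} /mm^2")
print(f"mean lesion size: {r.mean_lesion_size_um2:.3f} um^2")
```

Output:

```
lesions: 22 (ground truth 22)
lesion density: 2485.2 /mm^2
mean lesion size: 1.017 um^2
```

All 22 placed lesions are recovered; the density (2485/mm² over this
0.0089 mm² ROI) reflects the Poisson draw around the specified
2000/mm² regime, and the mean size ~1 μm² matches the micro-dominated
size law. A full six-group cohort with statistics:

```sh
xirplesion simulate --preset r349p-cohort --seed 3 --out sim/
xirplesion stats --readouts sim/cohort_readouts.csv --out sim/report/
```

The CLI also provides `train`, `select`, `quantify`, `concordance` and
`run` (full pipeline from a YAML config); `xirplesion --help` lists them.

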