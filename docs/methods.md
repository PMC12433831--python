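# Methods

This note documents the models, parameter choices and numerical decisions
behind `xirplesion`, and what the synthetic benchmarks do and do not show
about real tissue.

## Pixel classification

**Features.** The per-pixel descriptor is a standard texture/blobness
basis: at each smoothing scale σ ∈ {0.5, 1, 2, 4, 8} px the Gaussian-
smoothed intensity, Gaussian gradient magnitude, Laplacian of Gaussian and
the two eigenvalues of the σ-windowed structure tensor (5 scales × 5 base
features = 25 channels). All filters use reflect padding. The sampled
second-derivative kernel is not exactly zero-sum at small σ, so the LoG
channel subtracts the kernel's DC response times the smoothed image; a
constant image therefore maps to exactly zero in every derivative channel.
The feature manifest (names + scales) is stored with the classifier and
checked at inference; mismatched manifests are refused. The exact feature
composition of interactive pixel-classification tools is not published, so
this basis is a documented stand-in chosen for bright-blob detection, not
a claim of bit-compatibility with any particular tool.

**Model and training.** A binary MLP with one hidden layer of 32 logistic
units, trained by full-batch gradient descent on a weighted cross-entropy
loss (inverse class-frequency weights — annotations balance object counts,
not pixel counts), with a small L2 penalty (1e-4) for conditioning.
Each accepted step must not increase the loss (backtracking halves the
step until it decreases; the step grows by 1.1 after acceptance), so the
loss history is non-increasing by construction and training terminates
after at most 200 accepted steps or at a 1e-12 improvement floor. Features
are standardized to zero mean/unit variance using the training pixels'
statistics, stored per checkpoint. Annotated *ignore* pixels are negative
examples; unannotated pixels are excluded (sparse supervision).

**Checkpoints and selection.** One checkpoint per training image:
checkpoint *k* is retrained from the same seeded initialization on the
cumulative labeled pixels of images 1..*k*. Retraining from scratch (rather
than warm-starting) keeps every checkpoint exactly reproducible and
independent of the evolving feature standardizer. The deployed iteration
maximizes pooled pixel-level F1 on validation sections with ground-truth
masks; F1 jointly penalizes missed lesions and false positives, the two
criteria that matter for lesion counting. Ties break to the earliest
checkpoint.

**Coordinates.** 0-based, row-major; pixel centers at integer coordinates.
A pixel is inside a polygon iff its center lies strictly inside (even-odd
rule, holes supported). Annotations of different classes may not overlap.

## Morphometry

Connected components are computed with 8-neighbor connectivity (diagonal
pixel chains visually read as one lesion; the 4-connectivity alternative
remains available and is exercised against a brute-force flood-fill oracle
in the tests). Components are clipped to the ROI *before* size filtering,
so a lesion straddling the ROI border contributes only its inside pixels.
Area is pixel count × pixel size², with no sub-pixel boundary smoothing —
this matches the semantics of a pixel-classification output. The minimum
detection size (≥ 0.01 μm², inclusive) is inert at 0.13 μm/px because a
single pixel is already 0.0169 μm²; it becomes active at coarser
resolutions. The macrolesion rule is strict (> 10 μm²): at 0.13 μm/px a
591-pixel component (9.9879 μm²) is not a macrolesion and a 592-pixel
component (10.0048 μm²) is. Mean lesion size is computed after the
minimum-size filter (moot at the default pixel size). For a section with
zero lesions, mean size and macrolesion fraction are reported as missing
values, never zero, so group means are not deflated. Note that micro- vs
macrolesions can also be defined by sarcomere span in longitudinal
sections; this package implements only the cross-sectional area criterion.

## Statistical decision tree

Per metric and per group, normality is assessed with the Anderson–Darling
test (case-3 approximation for estimated mean and variance, via
statsmodels). "Similar standard deviation" means *both* Bartlett and
Brown–Forsythe (median-centered Levene) tests are non-significant at α;
either one significant routes to the unequal-variance branch. Branches:

- **ANOVA + Tukey HSD** — all groups normal, similar spread. Unadjusted
  pairwise Student t p-values are recorded alongside for the audit trail.
- **Welch ANOVA + Dunnett T3** — normal, unequal spread. The
  Brown–Forsythe ANOVA statistic is recorded alongside the Welch omnibus.
  Dunnett's T3 uses per-pair Welch t statistics with Welch–Satterthwaite
  degrees of freedom against the studentized-maximum-modulus distribution,
  evaluated by numerical integration over the chi density; for a family of
  one it reduces exactly to the Welch t test.
- **Kruskal–Wallis + Holm-corrected Mann–Whitney** — any group
  non-normal. Mann–Whitney p-values are exact (full-distribution) when
  min(n) ≤ 8 and the data are tie-free, otherwise normal approximation
  with tie correction.

Two-sample contrasts: both samples normal → two-sided F-test on variances
at α decides Student vs Welch t (the simplest variance-equality test
consistent with the t family); otherwise Mann–Whitney. All tests
two-tailed; α = 0.05; stars at 0.05/0.01/0.001/0.0001; summaries are
mean ± SEM. Every decision records its full audit trail (all normality and
variance p-values), and the branch is a pure function of that trail.

The six-group study analysis runs, per metric (lesion density, mean lesion
size, macrolesion density), a three-genotype omnibus within each exercise
condition, plus within-genotype sedentary-vs-exercised contrasts. The
contrast pairs are exposed explicitly; within-genotype condition contrasts
are the default "comparisons of interest" and are reported unadjusted, as
designated pairwise comparisons.

Interobserver concordance compares two readout tables matched on sample id:
per metric, Pearson r, an identity-line regression, the paired mean
difference with a paired t test, and per-investigator distribution
summaries. Identical tables give r = 1 and mean difference 0 by
construction — with fixed investigator input the pipeline is deterministic,
which is the computational content of "no interobserver variability".

## Synthetic tissue and cohorts

One simulated section is: a Voronoi fiber mosaic (per-cell level jitter
with CV 0.08 around a background of 80 counts, plus smooth Gaussian
texture of amplitude 8) as autofluorescent background; lesions placed by a
homogeneous spatial Poisson process (expected count = density × ROI area)
inside a smooth soleus-like blob ROI covering ~30–70% of the field; lesion
shapes are random-orientation ellipses (axis ratio U(1,3)) with areas from
a two-component lognormal mixture — a micro mode (σ_log 0.6) and a macro
mode centered at 20 μm² (σ_log 0.4) — spanning the 10 μm² boundary; per-
lesion peak 400 × U(0.8, 1.25) counts (peak:background = 5); then PSF blur
(σ 0.8 px), Poisson shot noise and Gaussian read noise (SD 4). The
canonical ground truth is the *pre-blur* footprint mask clipped to the
ROI; overlapping placements merge, and the ledger is recomputed from the
merged mask so ground truth stays self-consistent at high densities.

Cohort presets use the published group means of the R349P desmin knock-in
treadmill study as regime parameters (densities 1874/3473/16924 per mm²
sedentary and 5232/5468/18149 per mm² exercised for WT/HET/HOM; mean sizes
0.7/0.9/1.4 and 0.8/1.0/1.4 μm²; macrolesion densities 16/39/341 and
49/62/337 per mm²), with group sizes 8/9/9/9/10/12. For each group the
macro-mode weight is solved so the expected fraction of drawn areas above
10 μm² equals the group's macrolesion fraction, then the micro-mode mean
is solved to hit the target mean size. Between-animal variability is a
lognormal multiplier on density with CV 0.3 — a stand-in, since the true
animal-to-animal variance is not published as a printed statistic. By
default cohorts are ledger-only (counts and areas sampled over a 0.2 mm²
ROI, no rasterization), which is exact for everything the statistics stage
consumes; rendered cohorts are available for pixel-level end-to-end tests.

**What the benchmarks show — and don't.** The classifier benchmark
(320×320 px sections, 3 μm² mean lesion size, peak:background 5) measures
boundary-accurate pixel recovery under blur and noise; the density-recovery
benchmark (1024×1024 px at 2000/mm²) measures count fidelity. Real tissue
adds effects the simulator deliberately omits: staining batch variation,
connective-tissue autofluorescence structures, out-of-focus tiles,
longitudinal-section geometry and genuine biological shape variety.
Passing these benchmarks shows the pipeline is correct and calibrated, not
that a classifier trained on synthetic sections transfers to microscopy
data — on real data the classifier must be trained on real annotations, as
in the documented workflow.

**Power of the significance-pattern benchmark.** With CV 0.3 and the
study's group sizes, the sedentary-vs-exercised HET lesion-density
contrast (3473 → 5468/mm², n = 9 vs 9, d ≈ 1.45) has ≈ 0.8 power, and the
HOM null holds in ≈ 0.92 of cohorts; the full five-event pattern therefore
reproduces in only ~70% of simulated cohorts (measured 0.62–0.80 across
50-seed families). This is a property of the effect sizes, group sizes and
the assumed CV, not of the implementation: a single published detection of
a d ≈ 1.5 effect at n = 9 is itself a ~50–80% probability event.

## Reproducibility and numerics

All randomness flows from explicit integer seeds (numpy `default_rng`);
identical seeds give bit-identical images, ledgers, classifiers and CSV
outputs. Classifier persistence is a JSON manifest plus an `.npz` weights
file. The pipeline config round-trips losslessly through YAML and is
content-hashed; outputs produced under a different hash are never silently
overwritten. Degenerate inputs fail loudly: empty ROIs, constant groups
under ANOVA, single-class training or validation sets, out-of-bounds
polygons, mismatched feature manifests, and samples identical in both
groups of a two-sample test are all errors rather than silent defaults.

## Known limitations

- No multichannel colocalization, per-fiber lesion assignment, or
  automatic soleus segmentation (ROI definition is deliberately manual).
- The feature basis and network size approximate, but cannot replicate,
  the interactive tool used in the original workflow.
- The simulator's optics model (Gaussian PSF, Poisson+Gaussian noise) is
  phenomenological, not a physical photon simulation.
- The between-animal CV (0.3) is a tunable stand-in; conclusions about
  statistical power at cohort scale are conditional on it.
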