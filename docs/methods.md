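# Methods

## Problem and scope

Skeletal-muscle cross-sectional area (CSA) measured on a single axial CT
slice at the third lumbar vertebra (L3) is a standard surrogate for lean
body mass in body-composition research. Fat separates cleanly from other
tissue by Hounsfield unit (HU) thresholding, but muscle shares its HU
interval ([-29, 150] under intravenous contrast) with neighboring organs,
so intensity thresholding alone over-segments and manual correction is
slow. `musclemap` implements a fully automated alternative: a family of
fully convolutional networks (FCN-32s through FCN-2s) trained on
three-class label maps (Background / Muscle / Inside), preceded by linear
HU windowing and followed by HU-threshold removal of intramuscular fat.
All experiments here run on synthetic phantoms; no clinical data ships
with the package.

## The segmentation model

One VGG-style encoder of five stages (3x3 convolutions + ReLU, then 2x2
max pooling) produces features at strides 2, 4, 8, 16 and 32. A 1x1
convolution converts the deepest features into per-class score maps.  A
variant with fusion stride *s* refines these scores log2(32/*s*) times:
each refinement upsamples the running score map 2x with a learned
transposed convolution (initialized to bilinear interpolation) and adds a
zero-initialized 1x1 score projection of the matching encoder stage.  A
final learned upsampling restores input resolution, and per-pixel argmax
(ties to the lowest class index) yields the label map.  The "Inside"
class exists to teach the muscle/organ boundary; it is discarded when the
muscle mask is extracted.

The network, including all backward passes, is implemented directly in
NumPy (im2col convolutions against BLAS); a finite-difference gradient
check over the complete fusion ladder is part of the test suite.  With no
deep-learning framework in the dependency chain, training is CPU-only and
sized accordingly (below).

### Training recipe

Two presets:

* **full-scale preset** — unnormalized softmax loss (summed over pixels), SGD
  with momentum 0.9, minibatch 8, learning rate 1e-10, weight decay
  1e-12, 500 epochs, last model kept.  This reproduces the historical
  full-scale recipe and is exposed for completeness; it presumes a
  pretrained backbone and GPU-scale budgets.
* **desk preset (default)** — per-pixel-normalized cross-entropy,
  learning rate 0.05, momentum 0.9, weight decay 1e-6, minibatch 8, 30
  epochs, global gradient-norm clipping at 1.0.  Chosen so a
  width-reduced network (base width 8, i.e. encoder widths 8/16/32/64/64)
  trains from scratch on one CPU in under a minute per model at 128 px.
  Clipping matters: without it a freshly initialized network diverges
  under some window settings at this learning rate.  No validation-based
  model selection is performed in either preset; the final-epoch model is
  used.

No data augmentation, no class weighting.  Inputs are windowed gray
values rescaled to [0, 1] and centered at 0.5; the rescaling divides by
2^BIT - 1, so different bit depths reach the network on a common scale
while retaining their quantization loss.  `pretrained_backbone` exists as
a configuration field but no weights are bundled; constructing such a
network raises.

## HU windowing

The window transform is specified graphically in the radiology
literature; the exact discretization used here is floor binning on the
half-open window [WL - WW/2, WL + WW/2):

    g = clip(floor((HU - low) / WW * 2^BIT), 0, 2^BIT - 1)

This maps the window center to 2^(BIT-1), gives equal-width bins, and
makes bit-depth coarsening exact: the 6-bit image equals the 8-bit image
right-shifted two bits.  Pixels at gray 0 or 2^BIT - 1 are a superset of
the out-of-window pixels (in-window HU can land in the first or last
bin); the saturation test therefore uses images constructed to keep the
interior bins away from the extremes.

## HU thresholding

Muscle [-29, 150] and fat [-190, -30] intervals are closed on both ends;
with integer HU they partition the boundary unambiguously, and
real-valued HU strictly inside (-30, -29) belongs to neither.  The
thresholding baseline segments the full image (no body-region masking),
and intramuscular-fat post-processing always consumes the original HU
image rather than the windowed grayscale, because narrow windows (e.g.
WL 40 / WW 240) clip the fat range entirely.  Post-processing is
anti-extensive: it can only remove pixels from a predicted mask.

## The phantom generator

Each phantom emulates one L3-level slice at the fidelity the segmentation
task needs, not X-ray physics: air background (-1000 HU), an elliptical
body with a subcutaneous-fat rind (Background label, fat HU), a closed
elliptical muscle ring (Muscle), and an interior compartment (Inside)
holding visceral fat, 3 large elliptical organs with lean-tissue HU
overlapping muscle, and a posterior vertebral blob (400 HU).  Tissue HU is
a per-region base plus clipped Gaussian texture confined to the region's
interval.  Optional features reproduce known failure modes: intramuscular
fat pockets (fat HU, Muscle label — exactly the pixels post-processing
should remove; the generator records their count), and a subcutaneous
edema blob (muscle HU, Background label — the classic false positive).
Boundaries are blurred with a 0.6 px Gaussian as a partial-volume proxy
(labels stay crisp) and additive Gaussian noise (SD 10 HU x habitus)
models the higher noise of larger patients.  The `habitus` factor scales
body size and fat-rind thickness and defines three strata
(normal/overweight/obese: 0.85-1.0, 1.0-1.15, 1.15-1.3) used for
balanced cohort generation and seeded stratified train/test splits.
Default geometry: 128 px slices at 3.4 mm/px (~44 cm field of view);
512 px is supported.

What the phantom deliberately reproduces: the HU overlap between muscle
and organs (which defeats thresholding), the disjoint fat interval
(which makes post-processing exact on noiseless phantoms), the ring
topology, and habitus-dependent size/noise.  What it does not reproduce:
real anatomical shape variability and, importantly, within-tissue
*texture*.  Phantom tissues are near-piecewise-constant, so region
identity plus boundary geometry suffices for segmentation at any bit
depth — see the window-sweep caveat below.

## Study conditions and what the numbers mean

The standard study scale is: 128 px phantoms, 90-slice cohort split
60/30 balanced over the three habitus strata, desk training preset, all
seeded.  At this scale (fixed seeds 11/0):

* HU thresholding scores mean DSC ~0.80 on the held-out set — the organs
  and edema force its errors by construction.
* FCN-2s reaches mean DSC ~0.95 with CSA errors dominated by the
  intramuscular-fat convention below; the coarse FCN-32s trails it by
  several DSC points with markedly worse CSA error, and fusion-depth
  ordering (2s >= 8s >= 32s) holds to within 0.02.
* Ground-truth muscle masks *include* fat-pocket pixels (they are
  anatomically muscle compartment), while the evaluated prediction has
  them removed; this costs roughly f/2 in DSC and ~f in CSA at pocket
  fraction f and mirrors the systematic underestimation known for this
  pipeline family.
* Across window settings at 8 bit the DSC spread stays within a few
  hundredths at the standard seeds; occasionally (seed-dependent) one
  cell trains a few points worse and the spread approaches ~0.06, which
  is training variance, not a window effect.  The 4-bit wide-window
  cell, however, does **not**
  reliably degrade on phantoms: 16 gray levels still preserve all the
  region/boundary information piecewise-constant tissues offer.  The
  published degradation at 4 bit is driven by textural information loss
  on real CT, which the phantom does not model.  This is a documented
  limit of phantom-scale validation, not of the harness.

## Numerical and design choices

* Floor binning (vs rounding) in the window transform: documented above;
  all tests are written against it.
* Sample standard deviation (ddof = 1) in mean ± SD summaries; a single
  report yields SD = NaN rather than 0.
* DSC of two empty masks raises instead of defaulting to 1.0 — it cannot
  occur on valid phantoms, and silent defaults hide bugs.
* Float32 parameters and activations for training speed; float64 is used
  for gradient checks.  All randomness flows from explicit integer seeds
  through `numpy.random.SeedSequence`, so cohorts, loss histories and
  result tables are bit-reproducible.
* Max-pool gradient routes to the first maximum on ties; argmax
  prediction ties resolve to the lowest class index.

## Known limitations

Phantom-only validation (no deposited clinical cohort exists to test
against); single-slice 2D only; no VAT/SAT separation; the paper-scale
pretrained backbone is interface-only.  Absolute DSC values on phantoms
are optimistic relative to clinical data — phantom geometry is far more
regular — so only relative comparisons (architecture ordering, baseline
gap, window robustness) should be read as reproducing the published
findings.
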