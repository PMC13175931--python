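# Methods

## The enhancement model

`octnss` enhances a grayscale OCT B-scan by re-expressing every pixel in the
neutrosophic domain and equalizing the resulting confidence map rather than
the raw intensities.

For an image `I(x, y)` with extrema `Imin`, `Imax`:

1. **Normalization.** `IN = (I − Imin) / (Imax − Imin + ε)` with `ε = 1e-8`.
   The guard makes flat images well defined (they normalize to all zeros)
   and caps the output below 1.
2. **Gradient.** Sobel kernels `Sx`, `Sy = Sxᵀ` are applied to `IN` as
   cross-correlation with replicate padding; `Gd = √(Gx² + Gy²)`.
   Correlation sign conventions do not matter because only the magnitude is
   used. Replicate padding was chosen over zero padding so the image border
   is not itself detected as an edge. The raster mean is subtracted before
   correlating — a no-op analytically (the kernels sum to zero) that makes
   flat rasters come out exactly zero in floating point.
3. **Neutrosophic components.** Truth `T = IN`; indeterminacy
   `I = 1 − (Gd − Gdmin)/(Gdmax − Gdmin + ε)`; falsity `F = 1 − T`. The
   gradient normalization receives the same ε guard as step 1, so a
   constant image yields `I = 1` everywhere — maximal indeterminacy is the
   natural flat-image limit. All three maps are clamped to [0, 1] to absorb
   floating-point overshoot.
4. **Similarity to the ideal.** Each pixel's `(T, I, F)` triple is scored
   against the ideal alternative `A* = (1, 0, 0)` with a cosine similarity,
   which collapses to `S = T / √(T² + I² + F²)`. Because `F = 1 − T` the
   denominator is bounded below by √½; it is still guarded with
   `max(denom, ε)`, a guard that leaves regular pixels bit-identical.
   `S` is high for bright, smooth, unambiguous structure and is suppressed
   by indeterminacy, which is what de-emphasizes speckle-dominated regions.
5. **CLAHE.** `S` is quantized to 8 bits (`round(255·S)`, half away from
   zero) and passed through contrast-limited adaptive histogram
   equalization with clip limit 2.0 on an 8×8 tile grid, then divided by
   255 to give `Enorm ∈ [0, 1]`.
6. **Defuzzification.** `Ĩ = Enorm · (Imax − Imin) + Imin` returns the
   result to the source intensity range, so enhancement never moves pixel
   values outside the range the scan arrived with.

Every stage is deterministic; the pipeline is a pure function of the pixels
and the parameters.

### CLAHE details

No OpenCV-style binary dependency is used; the implementation is part of
the package. Semantics: per-tile 256-bin histograms; clip level
`clip × (tile area / 256)` — i.e. a multiple of the mean bin count —
floored at one count so tiny tiles are not clipped to nothing; excess mass
redistributed uniformly over all 256 bins in a single pass; per-tile
mapping `round(cdf · 255 / area)`; per-pixel bilinear interpolation between
the mappings of the four nearest tile centers, clamping outside the
outermost centers. Tile boundaries come from rounding a uniform partition,
so non-divisible image sizes produce tiles differing by at most one row or
column. The test suite checks this against an independently written
straight-line per-pixel reference.

Rounding throughout the 8-bit stages is half away from zero; this symmetric
choice minimizes bias where bracket notation leaves floor-vs-round open.

## Quality metrics

* **PSNR** `10·log10(R²/MSE)` with `R = 255`; identical images report +inf
  rather than raising, since comparing an image to itself is a legitimate
  degenerate case.
* **SSIM** uses the standard Wang et al. parameterization: Gaussian window
  σ = 1.5 with 11×11 support, `K1 = 0.01`, `K2 = 0.03`, data range 255,
  population covariance, and a filter-radius crop before averaging. It is
  authored from scipy filter primitives and cross-checked against
  scikit-image's implementation to 1e-6 in the tests.
* **Entropy** is the Shannon entropy of the 256-bin histogram of the 8-bit
  rendering, so values live in [0, 8] bits; the improvement statistic is
  `100·(H_enh − H_orig)/H_orig`, reported to one decimal with a leading
  sign. The eight published per-class entropy pairs reproduce their printed
  improvement percentages under exactly this arithmetic.
* **Classification metrics** (confusion matrix, weighted
  precision/recall/F1, per-class one-vs-rest ROC AUC) delegate to
  scikit-learn behind the package surface. Weighted averages were chosen
  over macro so the same headline numbers remain meaningful if a phantom
  set is imbalanced; on balanced sets the two coincide.

## The phantom generator

Real retinal OCT is emulated only to first order: smooth undulating
horizontal bands at fixed per-layer reflectivities (brightest band playing
the RPE), one of eight parametric lesion archetypes (dome elevation,
subretinal mass, fluid dome, cystoid pockets, hyperreflective dots, RPE
bumps, full-thickness foveal gap, or none), multiplicative gamma speckle
with shape 4 and mean 1 — the standard first-order speckle surrogate — and
an optional low-contrast preset that compresses intensities into the middle
half of the 8-bit range ([64, 191] support after rounding).

Per-image randomness is split into two streams derived from the seed: base
geometry + speckle in one, lesion parameters in the other, so phantoms
sharing a seed differ only inside the lesion mask across archetypes — a
property the tests rely on. Dataset trees derive per-image seeds from a
stable hash of (seed, split, class, index), making whole trees byte-identical
across runs and splits independent.

What passing tests on phantoms do **not** show: robustness to real OCT
artifacts (shadowing, motion, vendor-specific speckle statistics, intensity
banding), or clinically meaningful classification. The phantoms exist to
make every pipeline stage testable without an external dataset; archetype
geometry is deliberately cartoonish.

The default dataset scale is 23/4/4 images per class per split — a 1:100
scale model of the 2300/350/350 split of the public 8-class retinal OCT
collection the pipeline targets.

## The two-stage training harness

The schedule: a dropout(0.5) + softmax head on a frozen backbone trained
with Adam at lr 1e-3 (batch 32, 10 epochs), then the last 50 backbone
layers unfrozen and trained at lr 1e-4 for 20 epochs, with categorical
cross-entropy, rotation (≤15°) / zoom (≤10%) / translation (≤10%) /
brightness (±10%) / horizontal-flip augmentation on the training stream
only, early stopping on validation loss with best-weight restoration, and
reduce-on-plateau (factor 0.5, patience 2) down to lr 1e-6. Augmentation
magnitudes are fixed defaults for the named transform families; the
early-stopping patience defaults to 5 and is an explicit assumption.
"Last 50 layers" counts layers in the backbone's own enumeration order from
the output end.

The backbone is pluggable: anything exposing `layers`, `freeze_all()`,
`unfreeze_last(n)`, `feature_dim` and forward/backward. The shipped
backbone is a three-conv-block numpy network whose pooled feature output is
a 4×4 average-pool grid per channel rather than a single global average:
with only a handful of gradient steps available at desk scale, the head
needs many informative feature dimensions for the class logits to order
correctly, and lesion archetypes differ mainly in coarse geometry that a
global average discards. The backbone centers its [0, 1] inputs to [−1, 1]
internally, as pretrained backbones do with their own normalization. An
EfficientNet-class backbone is an extension point of the same protocol; its
pretrained weights are out of scope here.

Desk-scale runs (tests, acceptance script) override the input size to
64×64 and the epochs to 2+2 over the default 184/32/32 phantom dataset —
sizes chosen so a full two-stage run takes seconds on one CPU while still
demonstrably lowering the training loss and beating the 1/8 chance rate on
the test split (median over three seeds). Enhancement for training is best
precomputed to disk (`batch-enhance`) since the transform is deterministic
per image; the streams can also enhance on the fly.

Reproducibility: all randomness (dataset, shuffling, augmentation, dropout,
initialization) flows from explicit integer seeds through
`numpy.random.default_rng`; two runs with one seed produce bit-identical
training histories.

## Numerical and degenerate-input choices

* ε = 1e-8 on every min-max denominator; flat images are fixed points of
  the whole pipeline (they defuzzify to their own constant).
* 8-bit quantization and image writing round half away from zero and clamp.
* A zero-norm `(T, I, F)` triple is rejected in the general similarity
  (undefined cosine); the per-pixel map cannot produce one since `F = 1−T`.
* PSNR of identical images is +inf, SSIM of identical images is 1 exactly.
* 16-bit sources keep their native scale at read time; per-image
  normalization makes the pipeline scale-invariant, and training streams
  divide by the bit-depth maximum.

## Known limitations

* The phantom speckle is uncorrelated pixel-to-pixel; real OCT speckle has
  spatial correlation set by the point-spread function.
* The numpy backbone is intentionally small; nothing here speaks to
  full-scale transfer-learning accuracy on real data.
* CLAHE redistributes clipped mass in one uniform pass; iterative
  redistribution variants would differ in the last gray level for heavily
  clipped tiles.
* Entropy-based quality scoring rewards histogram spreading; it is a proxy
  for "information richness", not a perceptual quality measure.
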