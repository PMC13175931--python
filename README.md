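# octnss

Neutrosophic similarity-score (NSS) enhancement and a two-stage
fine-tuning harness for retinal OCT image classification.

Retinal OCT B-scans suffer from multiplicative speckle, weak local
contrast and ambiguous layer boundaries, which degrade both human reading
and CNN feature extraction. This package implements an enhancement
pipeline that maps each pixel into the neutrosophic domain — truth `T`
(normalized intensity), indeterminacy `I` (one minus the normalized Sobel
gradient magnitude) and falsity `F = 1 − T` — and scores it against the
ideal alternative `A* = (1, 0, 0)`:

```
S(x, y) = T / sqrt(T² + I² + F²)
```

The similarity map `S` is quantized to 8 bits, sharpened with CLAHE
(clip 2.0, 8×8 tiles) and defuzzified back onto the original intensity
range, yielding an image with stronger layer separation that never leaves
the source range. Around this core the package provides:

- `octnss.metrics` — PSNR, SSIM (Wang et al. parameterization), 256-bin
  Shannon entropy and the entropy-improvement percentage, plus multi-class
  classification reports (confusion matrix, weighted P/R/F1, one-vs-rest AUC);
- `octnss.phantom` — a seeded generator of layered-retina phantoms with
  mean-1 gamma speckle and eight lesion archetypes (AMD, CNV, CSR, DME,
  DR, DRUSEN, MH, NORMAL), emitting class-folder datasets;
- `octnss.harness` — a two-stage transfer-learning schedule (frozen-base
  head training at lr 1e-3, then unfreezing the last 50 backbone layers at
  lr 1e-4, with augmentation, dropout 0.5, early stopping and
  reduce-on-plateau) over a pluggable backbone, shipped with a small numpy
  CNN for CPU-scale runs.

It is intended for researchers evaluating neutrosophic preprocessing for
medical image classification, and as a fully testable reference of the
enhancement algorithm itself.

## Worked example

```python
import numpy as np
from octnss import PhantomSpec, generate_phantom, enhance_image, quality_report

phantom = generate_phantom(PhantomSpec(seed=4, contrast_preset="low"))
result = enhance_image(phantom)
report = quality_report(phantom, result.enhanced)
print(f"PSNR  {report.psnr_db:.2f} dB")
print(f"SSIM  {report.ssim:.4f}")
print(f"entropy {report.entropy_orig:.4f} -> {report.entropy_enh:.4f} bits "
      f"({report.entropy_improvement_pct:+.1f}%)")
```

prints

```
PSNR  26.90 dB
SSIM  0.9005
entropy 6.1637 -> 6.5636 bits (+6.5%)
```

The low-contrast phantom's histogram is confined to the middle half of the
8-bit range; enhancement spreads it back across the recorded range, which
is why the entropy (information richness of the 8-bit histogram) rises
while SSIM stays high (the layer structure is preserved). The same
command-line flow:

```bash
octnss phantom --out data --n-train 23 --n-val 4 --n-test 4 --seed 7
octnss enhance --in data/train/AMD/phantom_0000.png --out enhanced.png
octnss metrics --orig data/train/AMD/phantom_0000.png --enh enhanced.png --out report.csv
octnss train --data data --config plan.yaml --out run/
octnss evaluate --run run/ --data data
```

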